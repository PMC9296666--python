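"""Mixture deconvolution: estimate relative cell-type fractions.

Three interchangeable engines share one contract: given an aligned
signature matrix S (genes x types) and a mixture profile m (genes), return
raw coefficients that are clipped at zero and renormalized to the simplex.

* ``nnls``  — non-negative least squares, min ||S w - m||^2, w >= 0.
* ``nusvr`` — linear nu-support-vector regression of the (optionally
  z-scored) mixture on the z-scored signature columns, fitted over a grid
  of nu values; the fit whose clipped-and-renormalized coefficients best
  reconstruct the standardized mixture (lowest RMSE) wins, ties going to
  the smaller nu.
* ``dwls``  — iteratively reweighted NNLS with weights
  ``1 / max((S w)^2, damping)``, emphasising low-expression genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.svm import NuSVR

from .containers import FractionTable, MixtureSet, ValidationError

__all__ = [
    "EngineConfig",
    "align_features",
    "deconvolve_nnls",
    "deconvolve_nusvr",
    "deconvolve_dwls",
    "postprocess_fractions",
    "evaluate_fit",
    "deconvolve_all",
]

logger = logging.getLogger(__name__)

MIN_SHARED_GENES = 50


@dataclass(frozen=True)
class EngineConfig:
    """Deconvolution engine settings."""

    engine: str = "nusvr"
    nu_grid: tuple = (0.25, 0.5, 0.75)
    standardize: bool = True
    svr_c: float = 1.0
    dwls_damping: float = 1e-4
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.engine not in {"nusvr", "nnls", "dwls"}:
            raise ValidationError(f"unknown engine {self.engine!r}")
        if self.engine == "nusvr" and not self.nu_grid:
            raise ValidationError("nu_grid must be non-empty for the nusvr engine")
        if any(not 0 < nu < 1 for nu in self.nu_grid):
            raise ValidationError("nu values must lie in (0, 1)")
        if self.dwls_damping <= 0 or self.max_iter < 1 or self.tol <= 0:
            raise ValidationError("dwls_damping, max_iter and tol must be positive")


def align_features(
    signature: pd.DataFrame, mixtures: MixtureSet, min_shared: int = MIN_SHARED_GENES
) -> tuple[pd.DataFrame, MixtureSet]:
    """Restrict signature and mixtures to their shared genes, same order."""
    shared = signature.index.intersection(mixtures.values.index)
    if len(shared) < min_shared:
        raise ValidationError(
            f"only {len(shared)} shared genes between signature "
            f"({len(signature.index)}) and mixtures ({len(mixtures.values.index)}); "
            f"need at least {min_shared}"
        )
    logger.info("feature alignment: %d shared genes", len(shared))
    return (
        signature.loc[shared],
        MixtureSet(mixtures.values.loc[shared], truth=mixtures.truth),
    )


def deconvolve_nnls(signature: pd.DataFrame, mixture_column: np.ndarray) -> np.ndarray:
    """Non-negative least-squares coefficients for one mixture."""
    S = signature.to_numpy()
    cond = np.linalg.cond(S)
    if cond > 1e8:
        logger.warning("signature matrix is ill-conditioned (cond=%.3g)", cond)
    w, _ = scipy.optimize.nnls(S, np.asarray(mixture_column, dtype=float))
    return w


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def deconvolve_nusvr(
    signature: pd.DataFrame, mixture_column: np.ndarray, config: EngineConfig
) -> tuple[np.ndarray, float, float]:
    """Linear nu-SVR coefficients; returns (weights, chosen_nu, rmse).

    The signature is z-scored with its global mean and SD (one scalar pair
    for the whole matrix, preserving the relative scale of the cell-type
    columns) and the mixture with its own, when ``config.standardize`` is
    set. Each nu in the grid is fitted; the reconstruction RMSE of the
    clipped, sum-normalized coefficients against the (standardized) mixture
    selects the winner, ties toward smaller nu.
    """
    S = signature.to_numpy(dtype=float)
    m = np.asarray(mixture_column, dtype=float)
    if config.standardize:
        sd = S.std()
        S = (S - S.mean()) / (sd if sd > 0 else 1.0)
        m = _standardize(m)
    best = None
    for nu in sorted(config.nu_grid):
        try:
            model = NuSVR(kernel="linear", nu=nu, C=config.svr_c)
            model.fit(S, m)
        except Exception as exc:  # solver failure at this nu
            logger.warning("nu-SVR failed at nu=%.3g: %s", nu, exc)
            continue
        coef = np.asarray(model.coef_).ravel()
        clipped = np.clip(coef, 0.0, None)
        total = clipped.sum()
        recon = S @ (clipped / total) if total > 0 else np.zeros_like(m)
        rmse = float(np.sqrt(np.mean((recon - m) ** 2)))
        if best is None or rmse < best[2] - 1e-15:
            best = (coef, nu, rmse)
    if best is None:
        raise ValidationError("nu-SVR failed for every nu in the grid")
    return best


def deconvolve_dwls(
    signature: pd.DataFrame, mixture_column: np.ndarray, config: EngineConfig
) -> tuple[np.ndarray, int, bool]:
    """Damped weighted least squares; returns (weights, iterations, converged).

    Starts from the NNLS solution and reweights each gene by the inverse
    squared reconstruction, damped from below, until the weight vector
    stabilises.
    """
    S = signature.to_numpy(dtype=float)
    m = np.asarray(mixture_column, dtype=float)
    w = deconvolve_nnls(signature, m)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        recon = S @ w
        weights = 1.0 / np.maximum(recon**2, config.dwls_damping)
        sw = np.sqrt(weights)
        w_new, _ = scipy.optimize.nnls(S * sw[:, None], m * sw)
        denom = max(np.linalg.norm(w_new), 1e-12)
        if np.linalg.norm(w_new - w) / denom < config.tol:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        logger.warning("DWLS did not converge in %d iterations", config.max_iter)
    return w, it, converged


def postprocess_fractions(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip negatives and renormalize to the simplex.

    Returns ``(fractions, degenerate)``; a degenerate fit (all coefficients
    non-positive) yields an all-zero vector.
    """
    clipped = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    total = clipped.sum()
    if total <= 0:
        return np.zeros_like(clipped), True
    return clipped / total, False


def evaluate_fit(
    signature: pd.DataFrame, fractions: np.ndarray, mixture_column: np.ndarray
) -> tuple[float, float]:
    """RMSE and Pearson r of the reconstruction against the mixture."""
    m = np.asarray(mixture_column, dtype=float)
    recon = signature.to_numpy() @ np.asarray(fractions, dtype=float)
    rmse = float(np.sqrt(np.mean((recon - m) ** 2)))
    if recon.std() == 0 or m.std() == 0:
        return rmse, float("nan")
    r = float(np.corrcoef(recon, m)[0, 1])
    return rmse, r


def deconvolve_all(
    signature: pd.DataFrame,
    mixtures: MixtureSet,
    config: EngineConfig | None = None,
) -> FractionTable:
    """Deconvolve every mixture column with the configured engine.

    Per-column degeneracies are flagged in the stats frame, never raised.
    """
    config = config or EngineConfig()
    sig, mix = align_features(signature, mixtures)
    frac_cols = {}
    stats_rows = []
    for mixture_id in mix.values.columns:
        m = mix.values[mixture_id].to_numpy()
        meta: dict = {"mixture": mixture_id, "engine": config.engine}
        if config.engine == "nnls":
            raw = deconvolve_nnls(sig, m)
        elif config.engine == "dwls":
            raw, iters, converged = deconvolve_dwls(sig, m, config)
            meta.update(iterations=iters, converged=converged)
        else:
            raw, nu, _ = deconvolve_nusvr(sig, m, config)
            meta.update(nu=nu)
        fractions, degenerate = postprocess_fractions(raw)
        rmse, r = evaluate_fit(sig, fractions, m)
        meta.update(rmse=rmse, pearson_r=r, degenerate=degenerate)
        frac_cols[mixture_id] = fractions
        stats_rows.append(meta)
    fractions = pd.DataFrame(frac_cols, index=sig.columns)
    fractions.columns = mix.values.columns
    stats = pd.DataFrame(stats_rows).set_index("mixture")
    return FractionTable(fractions, stats)
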