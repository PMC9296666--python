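"""Cell-level quality control, normalization and pseudobulk aggregation.

QC removes, in order: cells with fewer than ``min_genes`` detected genes
(empty droplets/nuclei), cells whose mitochondrial count fraction exceeds a
per-sample threshold, and suspected doublets with detected-gene counts more
than ``doublet_k`` sample standard deviations above the per-sample median
(median and SD computed after the first two filters; the rule is applied
exactly once). Normalization is global scaling to a fixed total followed by
log1p. Pseudobulk profiles are arithmetic cluster means of the normalized
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix, QCReport, ValidationError

__all__ = [
    "QCThresholds",
    "SEX_GENES",
    "qc_filter_cells",
    "remove_sex_genes",
    "normalize_log1p",
    "gate_g0_g1",
    "pseudobulk_cluster_means",
]

# Sex-linked genes excluded to remove sex-specific effects.
SEX_GENES = ("Xist", "Tsix", "Eif2s3y", "Ddx3y", "Uty", "Kdm5d")


@dataclass(frozen=True)
class QCThresholds:
    """Cell QC thresholds.

    ``mito_max`` may be a single fraction applied to every sample or a
    mapping sample -> fraction (the threshold is set per sample).
    ``doublet_k`` multiplies the per-sample SD of detected-gene counts for
    the high-count doublet rule (conventional range 4-5).
    """

    min_genes: int = 1000
    mito_max: float | dict = 0.10
    doublet_k: float = 4.0
    mito_gene_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_genes < 1:
            raise ValidationError("min_genes must be >= 1")
        if self.doublet_k <= 0:
            raise ValidationError("doublet_k must be positive")

    def mito_max_for(self, sample: str) -> float:
        if isinstance(self.mito_max, dict):
            if sample not in self.mito_max:
                raise ValidationError(f"no mitochondrial threshold for sample {sample!r}")
            return float(self.mito_max[sample])
        return float(self.mito_max)


def qc_filter_cells(
    counts: CountMatrix,
    thresholds: QCThresholds,
    sample_of_cell: pd.Series | dict,
) -> tuple[CountMatrix, QCReport]:
    """Apply the three cell QC rules; returns filtered counts and a report."""
    samples = pd.Series(sample_of_cell)
    missing = counts.cell_ids.difference(samples.index)
    if len(missing):
        raise ValidationError(f"cells without sample assignment, e.g. {list(missing[:5])}")
    samples = samples.reindex(counts.cell_ids)

    detected = pd.Series(counts.detected_genes_per_cell(), index=counts.cell_ids)
    totals = pd.Series(counts.counts_per_cell(), index=counts.cell_ids)

    mito_mask = counts.gene_ids.str.lower().str.startswith(
        thresholds.mito_gene_prefix.lower()
    )
    mito_counts = pd.Series(
        np.asarray(counts.values[np.where(mito_mask)[0], :].sum(axis=0)).ravel(),
        index=counts.cell_ids,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = (mito_counts / totals).fillna(0.0)

    removed: dict[str, list] = {"min_genes": [], "mito": [], "doublet": []}

    low = detected < thresholds.min_genes
    removed["min_genes"] = list(counts.cell_ids[low])
    keep = ~low

    mito_limit = samples.map(thresholds.mito_max_for)
    high_mito = keep & (mito_frac > mito_limit)
    removed["mito"] = list(counts.cell_ids[high_mito])
    keep = keep & ~high_mito

    # Doublet rule: per-sample median/SD over cells surviving the first two
    # filters; applied once, no iteration.
    for sample in samples[keep].unique():
        in_sample = keep & (samples == sample)
        vals = detected[in_sample]
        if len(vals) < 2:
            continue
        cutoff = vals.median() + thresholds.doublet_k * vals.std(ddof=1)
        doublets = in_sample & (detected > cutoff)
        removed["doublet"].extend(list(counts.cell_ids[doublets]))
        keep = keep & ~doublets

    rows = []
    for rule, cells in removed.items():
        if not cells:
            continue
        per_sample = samples.loc[cells].value_counts()
        for sample, n in per_sample.items():
            rows.append({"sample": sample, "rule": rule, "cells_removed": int(n)})
    report_df = pd.DataFrame(rows, columns=["sample", "rule", "cells_removed"])

    warnings = []
    if not keep.any():
        warnings.append("all cells removed by QC; result is empty")
    filtered = counts.subset_cells(counts.cell_ids[keep])
    return filtered, QCReport(report_df, removed, warnings)


def remove_sex_genes(matrix, genes=SEX_GENES):
    """Drop the fixed sex-linked gene rows (case-insensitive id match)."""
    drop = {g.lower() for g in genes}
    keep = [g for g in matrix.gene_ids if g.lower() not in drop]
    if len(keep) == len(matrix.gene_ids):
        return matrix
    return matrix.subset_genes(keep)


def normalize_log1p(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Global-scaling normalization: log(1 + count/cell_total * scale_factor)."""
    totals = counts.counts_per_cell()
    if (totals == 0).any():
        bad = counts.cell_ids[totals == 0].tolist()[:5]
        raise ValidationError(f"cells with zero total count, e.g. {bad}")
    mat = sp.csc_matrix(counts.values, dtype=float)
    mat = mat.multiply(scale_factor / totals[None, :]).tocsr()
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(mat, counts.gene_ids, counts.cell_ids, scale_factor)


def gate_g0_g1(
    normalized: NormalizedMatrix,
    phase_calls: pd.Series | dict,
    gate_genes=("Top2a", "Mki67"),
    threshold: float = 1.0,
) -> pd.Series:
    """Split upstream G1 calls into G0/G1 on proliferation-marker expression.

    A cell called G1 upstream stays G1 only if any gate gene's normalized
    value is strictly above ``threshold``; otherwise it is relabelled G0.
    S and G2M calls pass through unchanged.
    """
    phases = pd.Series(phase_calls).reindex(normalized.cell_ids)
    if phases.isna().any():
        raise ValidationError("phase_calls must cover every cell")
    lower = {g.lower() for g in gate_genes}
    rows = [i for i, g in enumerate(normalized.gene_ids) if g.lower() in lower]
    if len(rows) < len(gate_genes):
        import warnings as _warnings

        _warnings.warn("some gate genes absent; treating them as all-zero")
    if rows:
        vals = normalized.dense()[rows, :]
        proliferating = (vals > threshold).any(axis=0)
    else:
        proliferating = np.zeros(len(normalized.cell_ids), dtype=bool)
    out = phases.copy()
    g1 = phases == "G1"
    out[g1 & ~proliferating] = "G0"
    return out


def pseudobulk_cluster_means(
    normalized: NormalizedMatrix, labels: pd.Series | dict
) -> NormalizedMatrix:
    """Gene-wise arithmetic mean of normalized expression per cluster."""
    labels = pd.Series(labels).reindex(normalized.cell_ids)
    if labels.isna().any():
        bad = normalized.cell_ids[labels.isna()].tolist()[:5]
        raise ValidationError(f"unlabelled cells, e.g. {bad}")
    clusters = sorted(labels.unique())
    if not clusters:
        raise ValidationError("no cluster labels provided")
    dense = normalized.dense()
    cols = np.column_stack(
        [dense[:, (labels == c).to_numpy()].mean(axis=1) for c in clusters]
    )
    return NormalizedMatrix(
        cols, normalized.gene_ids, pd.Index(clusters), normalized.scale_factor
    )
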