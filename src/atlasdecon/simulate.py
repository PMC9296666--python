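"""Seeded synthetic data: reference atlases, ortholog maps, gene-family
lists and tumour mixtures with known composition.

The generator emulates the structure the downstream stages assume: a
multi-timepoint reference atlas whose cell types carry disjoint planted
marker modules (negative-binomial counts with a multiplicative mean shift),
an injective cross-species ortholog map covering a configurable fraction of
genes, and pseudobulk "tumour" mixtures that are known convex combinations
of reference cell-type profiles plus truncated Gaussian noise.

All generators are pure functions of their arguments and a seed: identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, GeneExclusionSets, MixtureSet, ValidationError

__all__ = [
    "AtlasSpec",
    "generate_reference_atlas",
    "generate_ortholog_map",
    "generate_tumour_mixtures",
    "generate_gene_family_lists",
    "sample_ground_truth",
]


@dataclass(frozen=True)
class AtlasSpec:
    """Parameters of a synthetic reference atlas.

    Each of ``n_cell_types`` types receives a disjoint block of
    ``markers_per_type`` marker genes whose negative-binomial mean is
    ``marker_fold_change`` times the baseline in cells of that type.
    Per-cell library-size factors are log-normal with sigma
    ``library_size_scale``; the NB is parameterized by mean and size
    (``dispersion``), so Var = mu + mu^2/size.
    """

    n_cell_types: int = 8
    cells_per_type: int = 100
    n_genes: int = 2000
    markers_per_type: int = 50
    marker_fold_change: float = 8.0
    timepoint_of_type: dict = field(default_factory=dict)
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    library_size_scale: float = 0.2
    seed: int = 0
    type_labels: tuple = ()

    def labels(self) -> list[str]:
        if self.type_labels:
            return list(self.type_labels)
        return [f"type{i:02d}" for i in range(self.n_cell_types)]

    def validate(self) -> None:
        if self.n_cell_types < 1 or self.cells_per_type < 1 or self.n_genes < 1:
            raise ValidationError("n_cell_types, cells_per_type and n_genes must be positive")
        if self.markers_per_type < 1:
            raise ValidationError("markers_per_type must be positive")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValidationError(
                "markers_per_type x n_cell_types exceeds n_genes: marker sets "
                "of distinct types must be disjoint"
            )
        if self.marker_fold_change <= 1:
            raise ValidationError("marker_fold_change must exceed 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("baseline_mean and dispersion must be positive")
        if self.library_size_scale < 0:
            raise ValidationError("library_size_scale must be non-negative")
        if self.type_labels and len(set(self.type_labels)) != self.n_cell_types:
            raise ValidationError("type_labels must be unique, one per cell type")

    def marker_genes(self) -> dict:
        """Map type label -> list of its planted marker gene ids."""
        genes = [f"Gene{i:05d}" for i in range(self.n_genes)]
        m = self.markers_per_type
        return {
            lab: genes[i * m : (i + 1) * m] for i, lab in enumerate(self.labels())
        }


def generate_reference_atlas(spec: AtlasSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a seeded synthetic atlas.

    Returns the genes x cells count matrix and a per-cell annotation frame
    with columns cluster, sample, timepoint, reporter, malignant.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels()
    genes = [f"Gene{i:05d}" for i in range(spec.n_genes)]
    n_cells = spec.n_cell_types * spec.cells_per_type

    # Per-type mean profile: baseline everywhere, fold-change on own markers.
    mean_profiles = np.full((spec.n_genes, spec.n_cell_types), spec.baseline_mean)
    m = spec.markers_per_type
    for t in range(spec.n_cell_types):
        mean_profiles[t * m : (t + 1) * m, t] *= spec.marker_fold_change

    lib = rng.lognormal(mean=0.0, sigma=spec.library_size_scale, size=n_cells)
    r = spec.dispersion

    blocks = []
    for t in range(spec.n_cell_types):
        mu = (
            mean_profiles[:, [t]]
            * lib[t * spec.cells_per_type : (t + 1) * spec.cells_per_type][None, :]
        )
        p = r / (r + mu)
        blocks.append(sp.csr_matrix(rng.negative_binomial(r, p)))
    values = sp.hstack(blocks, format="csr")

    cell_ids = [f"cell{t:02d}_{i:04d}" for t in range(spec.n_cell_types)
                for i in range(spec.cells_per_type)]
    counts = CountMatrix(values, pd.Index(genes), pd.Index(cell_ids))

    cluster = np.repeat(labels, spec.cells_per_type)
    annot = pd.DataFrame(
        {
            "cluster": cluster,
            "sample": [f"S{(i % 2) + 1}" for i in range(n_cells)],
            "timepoint": [spec.timepoint_of_type.get(c, "T0") for c in cluster],
            "reporter": "positive",
            "malignant": "non_malignant",
        },
        index=counts.cell_ids,
    )
    return counts, annot


def generate_ortholog_map(
    genes, frac_one_to_one: float, seed: int, target_prefix: str = "HS_"
) -> pd.Series:
    """Map a fraction of source genes to unique target-species symbols.

    Returns a Series indexed by source id with target id values; unmapped
    genes are simply absent. The map is injective by construction.
    """
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise ValidationError("gene list must be non-empty")
    if genes.has_duplicates:
        raise ValidationError("duplicate source gene identifiers")
    if not 0.0 <= frac_one_to_one <= 1.0:
        raise ValidationError("frac_one_to_one must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_mapped = int(round(frac_one_to_one * len(genes)))
    chosen = np.sort(rng.choice(len(genes), size=n_mapped, replace=False))
    src = genes[chosen]
    return pd.Series([f"{target_prefix}{g.upper()}" for g in src], index=src)


def generate_tumour_mixtures(
    signature: pd.DataFrame,
    truth: pd.DataFrame,
    noise_sd: float,
    seed: int,
) -> MixtureSet:
    """Mix signature columns by known fractions and add truncated noise.

    Each mixture column is ``signature @ truth_column`` plus i.i.d. Gaussian
    noise with per-gene standard deviation ``noise_sd`` times the gene's mean
    signature expression, truncated at zero.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    unknown = truth.index.difference(signature.columns)
    if len(unknown):
        raise ValidationError(f"unknown cell types in ground truth: {list(unknown)}")
    truth_full = truth.reindex(signature.columns, fill_value=0.0)
    clean = signature.to_numpy() @ truth_full.to_numpy()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        scale = signature.to_numpy().mean(axis=1, keepdims=True)
        clean = clean + rng.normal(0.0, 1.0, clean.shape) * (noise_sd * scale)
    values = pd.DataFrame(
        np.clip(clean, 0.0, None), index=signature.index, columns=truth.columns
    )
    return MixtureSet(values, truth=truth_full)


def generate_gene_family_lists(genes, families: dict, seed: int) -> GeneExclusionSets:
    """Sample disjoint gene-family exclusion sets.

    ``families`` maps a family name (cell_cycle, ribosome, mitochondrial,
    apoptosis) to the fraction of genes it should contain; fractions must
    sum to less than 1 so sampling without replacement is possible.
    """
    genes = pd.Index(genes)
    bad = set(families) - set(GeneExclusionSets.FAMILIES)
    if bad:
        raise ValidationError(f"unknown gene families: {sorted(bad)}")
    if sum(families.values()) >= 1.0:
        raise ValidationError("family fractions must sum to less than 1")
    rng = np.random.default_rng(seed)
    pool = np.array(genes)
    rng.shuffle(pool)
    out: dict = {}
    start = 0
    for fam, frac in families.items():
        k = int(round(frac * len(genes)))
        out[fam] = frozenset(pool[start : start + k])
        start += k
    return GeneExclusionSets(**out)


def sample_ground_truth(
    cell_types,
    n_mixtures: int,
    seed: int,
    n_active: int = 3,
    alpha: float = 1.0,
    dominant_type: str | None = None,
    dominant_range: tuple = (0.6, 0.9),
    zero_types=(),
) -> pd.DataFrame:
    """Draw simplex ground-truth compositions for synthetic mixtures.

    Each mixture activates ``n_active`` randomly chosen cell types with
    Dirichlet(alpha) weights. If ``dominant_type`` is given, that type takes
    a fraction drawn uniformly from ``dominant_range`` in every mixture and
    the remainder is split over the other active types; types listed in
    ``zero_types`` are never activated (true fraction exactly 0).
    """
    cell_types = pd.Index(cell_types)
    rng = np.random.default_rng(seed)
    eligible = [t for t in cell_types if t not in set(zero_types) and t != dominant_type]
    if n_active > len(eligible) + (dominant_type is not None):
        raise ValidationError("n_active exceeds number of eligible cell types")
    truth = np.zeros((len(cell_types), n_mixtures))
    for j in range(n_mixtures):
        k_other = n_active - (1 if dominant_type is not None else 0)
        others = rng.choice(len(eligible), size=k_other, replace=False)
        if dominant_type is not None:
            dom = rng.uniform(*dominant_range)
            truth[cell_types.get_loc(dominant_type), j] = dom
            w = rng.dirichlet(np.full(k_other, alpha)) * (1.0 - dom)
        else:
            w = rng.dirichlet(np.full(k_other, alpha))
        for idx, frac in zip(others, w):
            truth[cell_types.get_loc(eligible[idx]), j] = frac
    return pd.DataFrame(
        truth, index=cell_types, columns=[f"mix{j:03d}" for j in range(n_mixtures)]
    )
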