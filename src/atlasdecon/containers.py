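"""Core in-memory containers for the deconvolution pipeline.

Matrices are oriented genes x cells (or genes x clusters / genes x mixtures)
throughout, mirroring the 10x Matrix Market triplet layout on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ValidationError",
    "CountMatrix",
    "NormalizedMatrix",
    "MixtureSet",
    "FractionTable",
    "GeneExclusionSets",
    "QCReport",
]


class ValidationError(ValueError):
    """An input violates a documented invariant."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what} identifiers, e.g. {dups}")


@dataclass
class CountMatrix:
    """Raw integer counts, genes x cells, stored sparse.

    Parameters
    ----------
    values
        Sparse matrix of shape ``(n_genes, n_cells)`` holding non-negative
        integer counts.
    gene_ids, cell_ids
        Unique identifiers for rows and columns respectively.
    """

    values: sp.spmatrix
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        data = self.values.data
        if data.size and (data.min() < 0 or np.any(data != np.round(data))):
            raise ValidationError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with nonzero count, per cell."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def subset_cells(self, keep: np.ndarray | list | pd.Index) -> "CountMatrix":
        idx = self.cell_ids.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            missing = pd.Index(keep)[idx < 0].tolist()[:5]
            raise KeyError(f"unknown cell ids, e.g. {missing}")
        return CountMatrix(self.values[:, idx], self.gene_ids, pd.Index(keep))

    def subset_genes(self, keep: np.ndarray | list | pd.Index) -> "CountMatrix":
        idx = self.gene_ids.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            missing = pd.Index(keep)[idx < 0].tolist()[:5]
            raise KeyError(f"unknown gene ids, e.g. {missing}")
        return CountMatrix(self.values[idx, :], pd.Index(keep), self.cell_ids)


@dataclass
class NormalizedMatrix:
    """Library-size normalized, log1p-transformed expression (genes x cells
    or genes x clusters)."""

    values: sp.spmatrix | np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    scale_factor: float = 10_000.0
    transform: str = "log1p"

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("normalized matrix shape mismatch")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, keep) -> "NormalizedMatrix":
        idx = self.gene_ids.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            missing = pd.Index(keep)[idx < 0].tolist()[:5]
            raise KeyError(f"unknown gene ids, e.g. {missing}")
        vals = self.values[idx, :] if sp.issparse(self.values) else self.values[idx, :]
        return NormalizedMatrix(vals, pd.Index(keep), self.cell_ids, self.scale_factor)


@dataclass
class MixtureSet:
    """Pseudobulk mixtures (genes x mixtures) with optional ground truth.

    ``truth`` is a cell-types x mixtures frame of simplex columns; it is
    attached only for synthetic data where the composition is known.
    """

    values: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "mixture")
        if self.truth is not None:
            if not self.truth.columns.equals(self.values.columns):
                raise ValidationError("truth columns must match mixture columns")
            sums = self.truth.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise ValidationError("ground-truth columns must sum to 1")

    @property
    def mixture_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class FractionTable:
    """Estimated relative fractions (cell-types x mixtures) plus per-mixture
    fit statistics.

    Every non-degenerate column is non-negative and sums to 1; degenerate
    fits (all-zero raw coefficients) are all-zero columns flagged in
    ``stats['degenerate']``.
    """

    fractions: pd.DataFrame
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.fractions.to_numpy()
        if vals.size and vals.min() < -1e-12:
            raise ValidationError("fractions must be non-negative")
        sums = vals.sum(axis=0)
        bad = ~(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12))
        if bad.any():
            raise ValidationError(
                f"fraction columns must sum to 1 (or 0 when degenerate); "
                f"offending mixtures: {list(self.fractions.columns[bad])[:5]}"
            )

    @property
    def cell_types(self) -> pd.Index:
        return self.fractions.index

    @property
    def mixture_ids(self) -> pd.Index:
        return self.fractions.columns


@dataclass
class GeneExclusionSets:
    """Gene families excluded from the signature: cell cycle / proliferation,
    ribosome biogenesis, mitochondrial and apoptosis-related genes."""

    cell_cycle: frozenset = frozenset()
    ribosome: frozenset = frozenset()
    mitochondrial: frozenset = frozenset()
    apoptosis: frozenset = frozenset()

    FAMILIES = ("cell_cycle", "ribosome", "mitochondrial", "apoptosis")

    def __post_init__(self) -> None:
        for fam in self.FAMILIES:
            setattr(self, fam, frozenset(getattr(self, fam)))

    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for fam in self.FAMILIES:
            out = out | getattr(self, fam)
        return out

    def as_dict(self) -> dict:
        return {fam: getattr(self, fam) for fam in self.FAMILIES}


@dataclass
class QCReport:
    """Per-sample, per-rule removal counts from cell quality control."""

    removals: pd.DataFrame  # columns: sample, rule, cells_removed
    removed_cells: dict  # rule -> list of cell ids
    warnings: list = field(default_factory=list)

    def total_removed(self) -> int:
        return int(self.removals["cells_removed"].sum())
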