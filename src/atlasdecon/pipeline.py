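"""End-to-end synthetic pipeline: atlas -> signature -> mixtures -> fractions.

This is the composition the library's pieces are designed for; it is used
by the ``pipeline`` CLI subcommand, the examples and the acceptance
instrumentation. Every stage is the public function of its module, so a run
here exercises exactly what a user would call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import preprocess, report, signature as sig
from .containers import FractionTable, MixtureSet
from .deconvolve import EngineConfig, deconvolve_all
from .report import MatchTable, RecoveryReport
from .simulate import (
    AtlasSpec,
    generate_gene_family_lists,
    generate_ortholog_map,
    generate_reference_atlas,
    generate_tumour_mixtures,
    sample_ground_truth,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_synthetic_pipeline", "build_synthetic_signature"]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for a full synthetic run."""

    atlas: AtlasSpec = field(default_factory=AtlasSpec)
    ortholog_frac: float = 0.9
    family_fracs: dict = field(default_factory=dict)
    n_mixtures: int = 40
    noise_sd: float = 0.05
    n_active_types: int = 3
    cutoff: float = 0.2
    engine: EngineConfig = field(default_factory=EngineConfig)
    scale_factor: float = 10_000.0
    pct_cutoff: float = 0.5
    lfc_cutoff: float = 0.5
    min_cells: int = 20
    seed: int = 0


@dataclass
class PipelineResult:
    signature: pd.DataFrame
    markers: pd.DataFrame
    mixtures: MixtureSet
    fractions: FractionTable
    matches: MatchTable
    recovery: RecoveryReport | None
    orthologs: pd.Series


def build_synthetic_signature(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate an atlas and run it through the signature construction.

    Returns (signature, marker table, ortholog map). The signature is in
    the target-species namespace when ``ortholog_frac > 0``.
    """
    counts, annot = generate_reference_atlas(config.atlas)
    counts = preprocess.remove_sex_genes(counts)
    normalized = preprocess.normalize_log1p(counts, config.scale_factor)
    labels = sig.drop_small_clusters(annot["cluster"], config.min_cells)
    markers = sig.wilcoxon_de_one_vs_rest(
        normalized, labels, config.pct_cutoff, config.lfc_cutoff
    )
    exclusions = generate_gene_family_lists(
        counts.gene_ids, config.family_fracs, seed=config.seed + 1
    )
    orthologs = generate_ortholog_map(
        counts.gene_ids, config.ortholog_frac, seed=config.seed + 2
    )
    signature = sig.build_signature_matrix(
        normalized, labels, markers, exclusions=exclusions, orthologs=orthologs
    )
    return signature, markers, orthologs


def run_synthetic_pipeline(config: PipelineConfig) -> PipelineResult:
    """Full parameter-recovery run with known ground truth."""
    signature, markers, orthologs = build_synthetic_signature(config)
    truth = sample_ground_truth(
        signature.columns,
        config.n_mixtures,
        seed=config.seed + 3,
        n_active=config.n_active_types,
    )
    mixtures = generate_tumour_mixtures(
        signature, truth, config.noise_sd, seed=config.seed + 4
    )
    fractions = deconvolve_all(signature, mixtures, config.engine)
    matches = report.threshold_matches(fractions, config.cutoff)
    recovery = report.recovery_metrics(fractions, mixtures.truth, config.cutoff)
    return PipelineResult(
        signature=signature,
        markers=markers,
        mixtures=mixtures,
        fractions=fractions,
        matches=matches,
        recovery=recovery,
        orthologs=orthologs,
    )
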