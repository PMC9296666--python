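"""Match calling, overlap summaries, hierarchical ordering and recovery
metrics for fraction tables.

A mixture "matches" a reference cell type when its estimated relative
fraction reaches the abundance cutoff (default 0.2, inclusive). Overlap
summaries count mixtures per exact match-set combination; hierarchical
clustering orders mixtures by their fraction vectors for heatmap-style
presentation and is serialized as a Newick tree.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .containers import FractionTable, ValidationError

__all__ = [
    "MatchTable",
    "RecoveryReport",
    "threshold_matches",
    "overlap_summary",
    "hierarchical_cluster_fractions",
    "recovery_metrics",
    "export_report",
]


@dataclass
class MatchTable:
    """Match calls per mixture at a fraction cutoff."""

    matches: dict  # mixture -> frozenset of matched cell types
    fractions: pd.DataFrame
    cutoff: float
    unmatched: list = field(default_factory=list)


@dataclass
class RecoveryReport:
    """Ground-truth recovery metrics for a synthetic run."""

    per_type_mae: pd.Series
    mean_abs_error: float
    pearson_r: float
    sensitivity: float
    specificity: float
    cutoff: float


def threshold_matches(fractions: FractionTable, cutoff: float = 0.2) -> MatchTable:
    """Call matched cell types: fraction >= cutoff (inclusive boundary)."""
    if not 0.0 < cutoff < 1.0:
        raise ValidationError("cutoff must lie in (0, 1)")
    matches = {}
    unmatched = []
    for mixture in fractions.mixture_ids:
        col = fractions.fractions[mixture]
        hit = frozenset(col.index[col >= cutoff])
        matches[mixture] = hit
        if not hit:
            unmatched.append(mixture)
    return MatchTable(matches, fractions.fractions, cutoff, unmatched)


def overlap_summary(matches: MatchTable) -> pd.DataFrame:
    """Count mixtures per exact combination of matched cell types.

    Only matched mixtures contribute; the counts therefore partition them.
    Sorted descending by count.
    """
    combos: dict = {}
    for mixture, hit in matches.matches.items():
        if not hit:
            continue
        key = tuple(sorted(hit))
        combos[key] = combos.get(key, 0) + 1
    rows = [
        {"cell_types": "+".join(k), "n_types": len(k), "n_mixtures": v}
        for k, v in combos.items()
    ]
    out = pd.DataFrame(rows, columns=["cell_types", "n_types", "n_mixtures"])
    return out.sort_values(
        ["n_mixtures", "cell_types"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _tree_to_newick(node, leaf_names, parent_height: float) -> str:
    if node.is_leaf():
        return f"{leaf_names[node.id]}:{parent_height - 0.0:.6g}"
    left = _tree_to_newick(node.left, leaf_names, node.dist)
    right = _tree_to_newick(node.right, leaf_names, node.dist)
    return f"({left},{right}):{parent_height - node.dist:.6g}"


def hierarchical_cluster_fractions(
    fractions: FractionTable,
    metric: str = "euclidean",
    linkage: str = "average",
) -> tuple[list, str, np.ndarray]:
    """Agglomerative clustering of mixtures on their fraction vectors.

    Returns the leaf order (mixture ids), a Newick serialization of the
    dendrogram, and the scipy linkage matrix. Ward linkage requires the
    euclidean metric.
    """
    if metric not in {"euclidean", "correlation"}:
        raise ValidationError(f"unsupported metric {metric!r}")
    if linkage not in {"average", "complete", "ward"}:
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValidationError("ward linkage requires the euclidean metric")
    data = fractions.fractions.to_numpy().T
    if data.shape[0] < 2:
        raise ValidationError("hierarchical clustering needs at least 2 mixtures")
    dists = ssd.pdist(data, metric=metric)
    Z = sch.linkage(dists, method=linkage)
    order = [fractions.mixture_ids[i] for i in sch.leaves_list(Z)]
    tree = sch.to_tree(Z)
    newick = (
        "("
        + ",".join(
            _tree_to_newick(child, list(fractions.mixture_ids), tree.dist)
            for child in (tree.left, tree.right)
        )
        + ");"
    )
    return order, newick, Z


def recovery_metrics(
    estimated: FractionTable, truth: pd.DataFrame, cutoff: float = 0.2
) -> RecoveryReport:
    """Compare estimated fractions against known composition.

    Positives are (type, mixture) pairs whose true fraction reaches the
    cutoff; sensitivity/specificity score the thresholded match calls
    against them.
    """
    est = estimated.fractions
    missing_types = est.index.symmetric_difference(truth.index)
    missing_mix = est.columns.symmetric_difference(truth.columns)
    if len(missing_types) or len(missing_mix):
        raise ValidationError(
            f"label mismatch between estimate and truth; types: "
            f"{list(missing_types)[:5]}, mixtures: {list(missing_mix)[:5]}"
        )
    truth = truth.loc[est.index, est.columns]
    err = (est - truth).abs()
    per_type_mae = err.mean(axis=1)
    e, t = est.to_numpy().ravel(), truth.to_numpy().ravel()
    pearson = float(np.corrcoef(e, t)[0, 1]) if e.std() and t.std() else float("nan")
    pos = t >= cutoff
    called = e >= cutoff
    sens = float((called & pos).sum() / pos.sum()) if pos.any() else float("nan")
    neg = ~pos
    spec = float((~called & neg).sum() / neg.sum()) if neg.any() else float("nan")
    return RecoveryReport(
        per_type_mae=per_type_mae,
        mean_abs_error=float(err.to_numpy().mean()),
        pearson_r=pearson,
        sensitivity=sens,
        specificity=spec,
        cutoff=cutoff,
    )


def export_report(
    fractions: FractionTable,
    matches: MatchTable,
    ordering: list,
    out_dir: str | Path,
    metadata: dict | None = None,
) -> dict:
    """Write the tabular report bundle; returns the paths written.

    Files: fractions.tsv (clustered order), match_table.tsv,
    overlap_summary.tsv, dendrogram.nwk, per-mixture stats.tsv and
    run_metadata.txt (config hash and versions).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out}: {exc}") from exc

    paths = {}
    ordered = fractions.fractions[list(ordering)]
    paths["fractions"] = out / "fractions.tsv"
    ordered.to_csv(paths["fractions"], sep="\t", index_label="cell_type")

    rows = [
        {
            "mixture": mix,
            "matched_types": "+".join(sorted(hit)) if hit else "",
            "unmatched": not hit,
        }
        for mix, hit in matches.matches.items()
    ]
    paths["matches"] = out / "match_table.tsv"
    pd.DataFrame(rows, columns=["mixture", "matched_types", "unmatched"]).to_csv(
        paths["matches"], sep="\t", index=False
    )

    paths["overlap"] = out / "overlap_summary.tsv"
    overlap_summary(matches).to_csv(paths["overlap"], sep="\t", index=False)

    if not fractions.stats.empty:
        paths["stats"] = out / "stats.tsv"
        fractions.stats.to_csv(paths["stats"], sep="\t")

    if len(ordering) >= 2:
        _, newick, _ = hierarchical_cluster_fractions(fractions)
        paths["dendrogram"] = out / "dendrogram.nwk"
        paths["dendrogram"].write_text(newick + "\n")

    meta = dict(metadata or {})
    meta.setdefault("cutoff", matches.cutoff)
    digest = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    import atlasdecon

    lines = [f"config_hash\t{digest}", f"atlasdecon_version\t{atlasdecon.__version__}"]
    lines += [f"{k}\t{v}" for k, v in sorted(meta.items())]
    paths["metadata"] = out / "run_metadata.txt"
    paths["metadata"].write_text("\n".join(lines) + "\n")
    return paths
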