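"""Cross-species signature-matrix construction.

One-vs-rest Wilcoxon rank-sum marker detection with pct / log-fold-change
cutoffs, small-cluster removal, gene-family exclusion, ortholog translation
and per-cluster average-expression assembly; plus the minimum-pairwise-LFC
marker ranking and shared-gene scoring used to compare tumour profiles with
their matched reference type.

Log fold changes follow the convention of cluster toolkits of the era:
natural log of ``(mean(expm1(x)) + 1)`` ratios between the cluster and the
rest, computed on log1p-normalized values.
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    GeneExclusionSets,
    NormalizedMatrix,
    ValidationError,
)

__all__ = [
    "rank_sum_test",
    "wilcoxon_de_one_vs_rest",
    "markers_by_cluster",
    "rank_markers_min_pairwise_lfc",
    "drop_small_clusters",
    "exclude_gene_families",
    "map_orthologs",
    "build_signature_matrix",
    "shared_signature_genes",
]

logger = logging.getLogger(__name__)

EXACT_MAX_TOTAL = 30  # pooled-size bound for the exact permutation p-value


@lru_cache(maxsize=64)
def _combination_indices(n: int, k: int) -> np.ndarray:
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), k)),
        dtype=np.int64,
    )
    return combos.reshape(-1, k)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value of the rank-sum statistic.

    Enumerates every assignment of the pooled values into the two groups;
    ties are handled naturally because mid-ranks are fixed by the pool.
    """
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    combos = _combination_indices(len(pooled), len(x))
    dist = ranks[combos].sum(axis=1)
    obs = ranks[: len(x)].sum()
    eps = 1e-9
    p_low = np.mean(dist <= obs + eps)
    p_high = np.mean(dist >= obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def rank_sum_test(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses an exact permutation enumeration when the pooled sample is small
    (total ``n <= 30``, ties supported) and the tie-corrected,
    continuity-corrected normal approximation otherwise.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both groups must be non-empty")
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    if method == "exact" or (method == "auto" and x.size + y.size <= EXACT_MAX_TOTAL):
        return float(u), _exact_rank_sum_p(x, y)
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u), float(res.pvalue)


def _cluster_profiles(dense: np.ndarray, masks: dict) -> tuple[dict, dict]:
    """Per-cluster mean expm1 expression and expressing-cell fraction."""
    mean_expm1, pct = {}, {}
    for c, mask in masks.items():
        sub = dense[:, mask]
        mean_expm1[c] = np.expm1(sub).mean(axis=1)
        pct[c] = (sub > 0).mean(axis=1)
    return mean_expm1, pct


def wilcoxon_de_one_vs_rest(
    normalized: NormalizedMatrix,
    labels: pd.Series | dict,
    pct_cutoff: float = 0.5,
    lfc_cutoff: float = 0.5,
    adj_p_cutoff: float | None = 0.05,
) -> pd.DataFrame:
    """One-vs-rest differential expression per cluster.

    Genes are screened by expressing-cell fraction (``pct_in >= pct_cutoff``)
    and average natural-log fold change (``avg_lfc >= lfc_cutoff``) before
    testing; surviving genes are tested cluster-vs-rest with the two-sided
    rank-sum test and BH-adjusted within each cluster. Rows failing
    ``adj_p < adj_p_cutoff`` are dropped when a cutoff is given.

    Returns a frame with columns gene, cluster, p_value, adj_p, avg_lfc,
    pct_in, pct_out.
    """
    labels = pd.Series(labels).reindex(normalized.cell_ids)
    if labels.isna().any():
        raise ValidationError("every cell must carry a cluster label")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValidationError("one-vs-rest DE requires at least two clusters")
    for c in clusters:
        if (labels == c).sum() < 2:
            raise ValidationError(f"cluster {c!r} has fewer than 2 cells")

    dense = normalized.dense()
    masks = {c: (labels == c).to_numpy() for c in clusters}
    genes = np.asarray(normalized.gene_ids)

    rows = []
    for c in clusters:
        in_mask = masks[c]
        out_mask = ~in_mask
        sub_in = dense[:, in_mask]
        sub_out = dense[:, out_mask]
        pct_in = (sub_in > 0).mean(axis=1)
        pct_out = (sub_out > 0).mean(axis=1)
        lfc = np.log(np.expm1(sub_in).mean(axis=1) + 1.0) - np.log(
            np.expm1(sub_out).mean(axis=1) + 1.0
        )
        cand = np.where((pct_in >= pct_cutoff) & (lfc >= lfc_cutoff))[0]
        if cand.size == 0:
            continue
        if in_mask.sum() + out_mask.sum() <= EXACT_MAX_TOTAL:
            pvals = np.array(
                [rank_sum_test(sub_in[g], sub_out[g])[1] for g in cand]
            )
        else:
            res = scipy.stats.mannwhitneyu(
                sub_in[cand], sub_out[cand], alternative="two-sided",
                method="asymptotic", axis=1,
            )
            pvals = np.atleast_1d(res.pvalue)
        adj = multipletests(pvals, method="fdr_bh")[1]
        for g, p, q in zip(cand, pvals, adj):
            rows.append(
                {
                    "gene": genes[g],
                    "cluster": c,
                    "p_value": float(p),
                    "adj_p": float(q),
                    "avg_lfc": float(lfc[g]),
                    "pct_in": float(pct_in[g]),
                    "pct_out": float(pct_out[g]),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["gene", "cluster", "p_value", "adj_p", "avg_lfc", "pct_in", "pct_out"],
    )
    if adj_p_cutoff is not None and len(table):
        table = table[table["adj_p"] < adj_p_cutoff].reset_index(drop=True)
    return table


def markers_by_cluster(marker_table: pd.DataFrame) -> dict:
    """Group a marker table into cluster -> list of retained genes."""
    return {
        c: list(sub["gene"]) for c, sub in marker_table.groupby("cluster", sort=True)
    }


def rank_markers_min_pairwise_lfc(
    normalized: NormalizedMatrix,
    labels: pd.Series | dict,
    de_genes: dict,
) -> dict:
    """Rank each cluster's DE genes by their minimum pairwise fold change.

    For cluster ``c`` and gene ``g`` the score is the minimum over every
    other cluster ``c'`` of the natural-log fold change of ``c`` vs ``c'``;
    a high minimum means the gene distinguishes the cluster from all
    others, not just from the pooled rest.
    """
    labels = pd.Series(labels).reindex(normalized.cell_ids)
    if labels.isna().any():
        raise ValidationError("every cell must carry a cluster label")
    clusters = sorted(labels.unique())
    dense = normalized.dense()
    masks = {c: (labels == c).to_numpy() for c in clusters}
    mean_expm1, _ = _cluster_profiles(dense, masks)
    log_mean = {c: np.log(mean_expm1[c] + 1.0) for c in clusters}
    gene_index = pd.Index(normalized.gene_ids)

    out = {}
    for c, gene_list in de_genes.items():
        if c not in masks:
            raise ValidationError(f"unknown cluster {c!r} in de_genes")
        if not gene_list:
            out[c] = pd.DataFrame(columns=["gene", "min_pairwise_lfc"])
            continue
        idx = gene_index.get_indexer(pd.Index(gene_list))
        if (idx < 0).any():
            bad = [g for g, i in zip(gene_list, idx) if i < 0][:5]
            raise ValidationError(f"de_genes not in matrix, e.g. {bad}")
        others = [o for o in clusters if o != c]
        pairwise = np.column_stack([log_mean[c][idx] - log_mean[o][idx] for o in others])
        min_lfc = pairwise.min(axis=1)
        ranked = (
            pd.DataFrame({"gene": gene_list, "min_pairwise_lfc": min_lfc})
            .sort_values("min_pairwise_lfc", ascending=False, kind="mergesort")
            .reset_index(drop=True)
        )
        out[c] = ranked
    return out


def drop_small_clusters(labels: pd.Series | dict, min_cells: int = 20) -> pd.Series:
    """Remove clusters with fewer than ``min_cells`` cells from the labels.

    Clusters at exactly the boundary are kept. Returns the label series
    restricted to cells of surviving clusters.
    """
    labels = pd.Series(labels)
    sizes = labels.value_counts()
    dropped = sizes[sizes < min_cells].index.tolist()
    if len(dropped) == len(sizes):
        raise ValidationError("all clusters fall below min_cells")
    if dropped:
        logger.info("dropping %d small clusters: %s", len(dropped), dropped)
    return labels[~labels.isin(dropped)]


def exclude_gene_families(genes, sets: GeneExclusionSets) -> list:
    """Remove the union of the exclusion families; input order preserved."""
    excluded = sets.union()
    return [g for g in genes if g not in excluded]


def map_orthologs(matrix, orthologs: pd.Series, policy: str = "one_to_one_only"):
    """Translate matrix rows into the target-species gene namespace.

    Rows without an ortholog are dropped; under ``one_to_one_only`` any
    source genes sharing a target symbol are all dropped, so the retained
    map is injective. Accepts a genes-indexed DataFrame or a
    NormalizedMatrix and returns the same type.
    """
    if policy not in {"one_to_one_only", "first"}:
        raise ValidationError(f"unknown ortholog policy {policy!r}")
    if isinstance(matrix, NormalizedMatrix):
        frame = matrix.to_frame()
        mapped = map_orthologs(frame, orthologs, policy)
        return NormalizedMatrix(
            mapped.to_numpy(), mapped.index, matrix.cell_ids, matrix.scale_factor
        )
    frame: pd.DataFrame = matrix
    sub = orthologs[orthologs.index.isin(frame.index)]
    if sub.empty:
        raise ValidationError("no matrix gene has an ortholog mapping")
    if policy == "one_to_one_only":
        dup = sub.duplicated(keep=False)
        n_dropped = int(dup.sum())
        if n_dropped:
            logger.info("dropping %d sources sharing a target symbol", n_dropped)
        sub = sub[~dup]
    else:
        sub = sub[~sub.duplicated(keep="first")]
    if sub.empty:
        raise ValidationError("ortholog resolution removed every mapped gene")
    logger.info(
        "ortholog mapping: %d of %d genes retained", len(sub), len(frame.index)
    )
    out = frame.loc[sub.index].copy()
    out.index = pd.Index(sub.to_numpy())
    return out


def build_signature_matrix(
    normalized: NormalizedMatrix,
    labels: pd.Series | dict,
    markers: pd.DataFrame,
    exclusions: GeneExclusionSets | None = None,
    orthologs: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the signature matrix from retained DE genes.

    The gene universe is the union of each cluster's retained DE genes,
    minus the exclusion families, translated through the ortholog map when
    given; values are per-cluster arithmetic means of normalized expression.
    """
    labels = pd.Series(labels)
    cells = pd.Index(labels.index)
    idx = normalized.cell_ids.get_indexer(cells)
    if (idx < 0).any():
        raise ValidationError("labels refer to cells absent from the matrix")

    universe = list(pd.unique(markers["gene"]))
    if not universe:
        raise ValidationError("marker table is empty: no DE genes to assemble")
    if exclusions is not None:
        universe = exclude_gene_families(universe, exclusions)
        if not universe:
            raise ValidationError("gene-family exclusion emptied the signature")

    dense = normalized.dense()[:, idx]
    gene_index = pd.Index(normalized.gene_ids)
    gidx = gene_index.get_indexer(pd.Index(universe))
    if (gidx < 0).any():
        bad = [g for g, i in zip(universe, gidx) if i < 0][:5]
        raise ValidationError(f"marker genes missing from matrix, e.g. {bad}")
    clusters = sorted(labels.unique())
    cols = np.column_stack(
        [dense[np.ix_(gidx, (labels == c).to_numpy())].mean(axis=1) for c in clusters]
    )
    sig = pd.DataFrame(cols, index=pd.Index(universe), columns=clusters)

    if orthologs is not None:
        sig = map_orthologs(sig, orthologs)
        if sig.empty:
            raise ValidationError("ortholog mapping emptied the signature")
    return sig


def shared_signature_genes(
    signature: pd.DataFrame,
    tumour_profile: pd.Series,
    matched_type: str,
    top_n: int = 50,
    expression_floor: float = 0.5,
) -> pd.DataFrame:
    """Genes shared between a tumour profile and its matched reference type.

    The score is the difference in average normalized expression (tumour
    minus reference). Genes where both values exceed the expression floor
    are ranked by ascending absolute difference, ties broken toward higher
    shared expression, so genes highly expressed in both with small
    difference rank first.
    """
    if matched_type not in signature.columns:
        raise ValidationError(f"unknown cell type {matched_type!r}")
    common = signature.index.intersection(tumour_profile.index)
    if common.empty:
        raise ValidationError("tumour profile shares no genes with the signature")
    ref = signature.loc[common, matched_type]
    tum = tumour_profile.loc[common]
    diff = tum - ref
    shared_level = np.minimum(tum.to_numpy(), ref.to_numpy())
    table = pd.DataFrame(
        {
            "tumour": tum,
            "reference": ref,
            "difference": diff,
            "shared_level": shared_level,
        },
        index=common,
    )
    eligible = table[(table["tumour"] > expression_floor) & (table["reference"] > expression_floor)]
    ranked = eligible.assign(abs_difference=eligible["difference"].abs()).sort_values(
        ["abs_difference", "shared_level"],
        ascending=[True, False],
        kind="mergesort",
    )
    return ranked.drop(columns="abs_difference").head(top_n).rename_axis("gene")
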