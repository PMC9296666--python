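"""Build a cross-species signature matrix from a synthetic atlas.

Pipeline: normalize -> one-vs-rest Wilcoxon markers (pct >= 0.5 and
natural-log fold change >= 0.5) -> exclude gene families -> translate to
the target-species namespace through an injective ortholog map -> average
normalized expression per cluster over the retained genes.
"""

import atlasdecon as ad

spec = ad.AtlasSpec(n_cell_types=4, cells_per_type=150, n_genes=800,
                    markers_per_type=25, marker_fold_change=8.0, seed=1)
counts, annot = ad.generate_reference_atlas(spec)
counts = ad.remove_sex_genes(counts)
normalized = ad.normalize_log1p(counts, scale_factor=10_000)

labels = ad.drop_small_clusters(annot["cluster"], min_cells=20)
markers = ad.wilcoxon_de_one_vs_rest(normalized, labels,
                                     pct_cutoff=0.5, lfc_cutoff=0.5)
print(f"marker table: {len(markers)} (gene, cluster) rows")
print(markers.groupby("cluster").size())

exclusions = ad.generate_gene_family_lists(
    counts.gene_ids, {"cell_cycle": 0.02, "ribosome": 0.02}, seed=2
)
orthologs = ad.generate_ortholog_map(counts.gene_ids, 0.9, seed=3)
signature = ad.build_signature_matrix(normalized, labels, markers,
                                      exclusions=exclusions,
                                      orthologs=orthologs)
print(f"signature: {signature.shape[0]} genes x {signature.shape[1]} cell types")
print(signature.head())
# each entry is the mean log1p-normalized expression of that gene over the
# cluster's cells; rows are target-species symbols, so a tumour profile in
# that namespace can be regressed on these columns directly

ranked = ad.rank_markers_min_pairwise_lfc(
    normalized, labels, ad.markers_by_cluster(markers)
)
top = ranked["type00"].head(5)
print("\ntop type00 markers by minimum pairwise LFC:")
print(top.to_string(index=False))
# a large minimum pairwise LFC means the gene separates the cluster from
# EVERY other cluster, not just from the pooled rest
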