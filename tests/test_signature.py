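import numpy as np
import pandas as pd
import pytest

import atlasdecon as ad
from atlasdecon.signature import markers_by_cluster, rank_sum_test

from _oracles import cluster_mean, exact_rank_sum_p


class TestRankSumTest:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 11, size=2)
        # count-like data with ties
        x = rng.negative_binomial(2, 0.4, n1).astype(float)
        y = rng.negative_binomial(2, 0.3, n2).astype(float)
        _, p = rank_sum_test(x, y)
        p_oracle = exact_rank_sum_p(x, y)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_separated_groups_give_small_p(self):
        x = np.arange(10, 20, dtype=float)
        y = np.arange(0, 10, dtype=float)
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_asymptotic_path_for_large_samples(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1.0, 60)
        y = rng.normal(0.0, 1.0, 60)
        _, p = rank_sum_test(x, y)
        assert 0 < p < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ad.ValidationError):
            rank_sum_test([], [1.0])


class TestWilcoxonDE:
    def test_clean_marker_passes_all_filters(self):
        # gene 0 expressed (value 2) in every cluster-A cell, zero elsewhere
        vals = np.zeros((3, 100))
        vals[0, :50] = 2.0
        vals[1, :] = 1.0  # constant gene: lfc 0, excluded
        vals[2, 50:] = 2.0
        norm = ad.NormalizedMatrix(vals, ["mkA", "const", "mkB"],
                                   [f"c{i}" for i in range(100)])
        labels = pd.Series(["A"] * 50 + ["B"] * 50, index=norm.cell_ids)
        table = ad.wilcoxon_de_one_vs_rest(norm, labels)
        rowA = table[(table.gene == "mkA") & (table.cluster == "A")]
        assert len(rowA) == 1
        assert rowA.pct_in.iloc[0] == 1.0
        assert rowA.p_value.iloc[0] < 1e-6
        assert "const" not in set(table.gene)

    def test_pct_cutoff_excludes_sparse_marker(self):
        rng = np.random.default_rng(0)
        vals = np.zeros((2, 100))
        on = rng.choice(50, size=20, replace=False)  # 40% of cluster A
        vals[0, on] = 3.0
        vals[1, 50:] = 2.0
        norm = ad.NormalizedMatrix(vals, ["sparse", "mkB"],
                                   [f"c{i}" for i in range(100)])
        labels = pd.Series(["A"] * 50 + ["B"] * 50, index=norm.cell_ids)
        table = ad.wilcoxon_de_one_vs_rest(norm, labels)
        assert ("sparse", "A") not in set(zip(table.gene, table.cluster))

    def test_single_cluster_rejected(self, small_normalized):
        labels = pd.Series("A", index=small_normalized.cell_ids)
        with pytest.raises(ad.ValidationError, match="two clusters"):
            ad.wilcoxon_de_one_vs_rest(small_normalized, labels)

    def test_planted_markers_recovered(self, small_spec, small_normalized, small_labels):
        table = ad.wilcoxon_de_one_vs_rest(small_normalized, small_labels)
        found = markers_by_cluster(table)
        for lab, planted in small_spec.marker_genes().items():
            recovered = set(found.get(lab, [])) & set(planted)
            assert len(recovered) / len(planted) >= 0.9


class TestMinPairwiseLFC:
    def test_arithmetic_three_clusters(self):
        # cluster means on the log scale: A=3, B=1, C=2 for one gene
        vals = np.array([[3.0] * 4 + [1.0] * 4 + [2.0] * 4])
        norm = ad.NormalizedMatrix(vals, ["g"], [f"c{i}" for i in range(12)])
        labels = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=norm.cell_ids)
        ranked = ad.rank_markers_min_pairwise_lfc(norm, labels, {"A": ["g"]})
        assert ranked["A"].min_pairwise_lfc.iloc[0] == pytest.approx(1.0)

    def test_negative_minimum_ranks_last(self):
        vals = np.array([
            [3.0] * 4 + [1.0] * 4 + [4.0] * 4,   # higher than B, lower than C
            [3.0] * 4 + [1.0] * 4 + [2.0] * 4,   # higher than both
        ])
        norm = ad.NormalizedMatrix(vals, ["mixed", "clean"],
                                   [f"c{i}" for i in range(12)])
        labels = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=norm.cell_ids)
        ranked = ad.rank_markers_min_pairwise_lfc(
            norm, labels, {"A": ["mixed", "clean"]}
        )["A"]
        assert list(ranked.gene) == ["clean", "mixed"]
        assert ranked.min_pairwise_lfc.iloc[1] < 0

    def test_planted_markers_top_ranked_vs_bruteforce(
        self, small_spec, small_normalized, small_labels
    ):
        planted = small_spec.marker_genes()
        lab = small_spec.labels()[0]
        de = {lab: planted[lab] + planted[small_spec.labels()[1]][:5]}
        ranked = ad.rank_markers_min_pairwise_lfc(small_normalized, small_labels, de)[lab]
        # own markers all outrank the other type's markers
        top = list(ranked.gene[: len(planted[lab])])
        assert set(top) == set(planted[lab])
        # brute-force recomputation of one gene's min pairwise LFC
        gene = planted[lab][0]
        dense = small_normalized.dense()
        gi = small_normalized.gene_ids.get_loc(gene)
        logmeans = {
            c: np.log(np.expm1(dense[gi, (small_labels == c).to_numpy()]).mean() + 1)
            for c in small_labels.unique()
        }
        expected = min(logmeans[lab] - logmeans[c] for c in logmeans if c != lab)
        got = float(ranked.set_index("gene").loc[gene, "min_pairwise_lfc"])
        assert got == pytest.approx(expected, rel=1e-9)


class TestClusterAndGeneFilters:
    def test_drop_small_clusters_boundary(self):
        labels = pd.Series(["A"] * 20 + ["B"] * 5 + ["C"] * 25)
        kept = ad.drop_small_clusters(labels, min_cells=20)
        assert set(kept.unique()) == {"A", "C"}  # 20 kept at boundary

    def test_drop_small_clusters_identity_and_error(self):
        labels = pd.Series(["A", "B"])
        assert ad.drop_small_clusters(labels, min_cells=1).equals(labels)
        with pytest.raises(ad.ValidationError, match="below min_cells"):
            ad.drop_small_clusters(labels, min_cells=10)

    def test_exclude_gene_families(self):
        sets = ad.GeneExclusionSets(
            mitochondrial=frozenset({"mt1"}),
            cell_cycle=frozenset({"ccnb1", "both"}),
            apoptosis=frozenset({"both"}),
        )
        out = ad.exclude_gene_families(["a", "mt1", "ccnb1", "both", "b"], sets)
        assert out == ["a", "b"]
        empty = ad.GeneExclusionSets()
        assert ad.exclude_gene_families(["a", "b"], empty) == ["a", "b"]


class TestOrthologMapping:
    def test_injective_map_renames_all(self):
        frame = pd.DataFrame(np.eye(3), index=["a", "b", "c"], columns=["T1", "T2", "T3"])
        orth = pd.Series(["A", "B", "C"], index=["a", "b", "c"])
        out = ad.map_orthologs(frame, orth)
        assert list(out.index) == ["A", "B", "C"]
        np.testing.assert_allclose(out.to_numpy(), frame.to_numpy())

    def test_unmapped_gene_dropped(self):
        frame = pd.DataFrame(np.ones((2, 1)), index=["a", "b"], columns=["T"])
        out = ad.map_orthologs(frame, pd.Series(["A"], index=["a"]))
        assert list(out.index) == ["A"]

    def test_shared_target_drops_both_sources(self):
        frame = pd.DataFrame(np.ones((3, 1)), index=["a", "b", "c"], columns=["T"])
        orth = pd.Series(["X", "X", "C"], index=["a", "b", "c"])
        out = ad.map_orthologs(frame, orth, policy="one_to_one_only")
        assert list(out.index) == ["C"]

    def test_empty_intersection_rejected(self):
        frame = pd.DataFrame(np.ones((1, 1)), index=["a"], columns=["T"])
        with pytest.raises(ad.ValidationError, match="no matrix gene"):
            ad.map_orthologs(frame, pd.Series(["Z"], index=["z"]))


class TestBuildSignature:
    def test_entries_equal_bruteforce_cluster_means(
        self, small_normalized, small_labels, small_signature
    ):
        dense = small_normalized.dense()
        gidx = small_normalized.gene_ids.get_indexer(small_signature.index)
        for ct in small_signature.columns:
            mask = (small_labels == ct).to_numpy()
            expected = cluster_mean(dense[gidx, :], mask)
            np.testing.assert_allclose(small_signature[ct].to_numpy(), expected,
                                       atol=1e-12)

    def test_excluded_marker_absent(self, small_spec, small_normalized, small_labels):
        planted = small_spec.marker_genes()
        victim = planted[small_spec.labels()[0]][0]
        markers = ad.wilcoxon_de_one_vs_rest(small_normalized, small_labels)
        sets = ad.GeneExclusionSets(cell_cycle=frozenset({victim}))
        signature = ad.build_signature_matrix(
            small_normalized, small_labels, markers, exclusions=sets
        )
        assert victim not in signature.index

    def test_exclusion_ortholog_order_invariance(
        self, small_normalized, small_labels
    ):
        markers = ad.wilcoxon_de_one_vs_rest(small_normalized, small_labels)
        genes = small_normalized.gene_ids
        orth = ad.generate_ortholog_map(genes, 0.8, seed=6)
        sets = ad.generate_gene_family_lists(genes, {"ribosome": 0.1}, seed=7)
        sig_a = ad.build_signature_matrix(
            small_normalized, small_labels, markers, exclusions=sets, orthologs=orth
        )
        # manual reverse order: ortholog-map the unexcluded signature, then
        # drop rows whose source genes are excluded
        sig_full = ad.build_signature_matrix(
            small_normalized, small_labels, markers, orthologs=orth
        )
        excluded_targets = {orth[g] for g in sets.union() if g in orth.index}
        sig_b = sig_full[~sig_full.index.isin(excluded_targets)]
        pd.testing.assert_frame_equal(sig_a.sort_index(), sig_b.sort_index())

    def test_study_scale_signature_size(self):
        # an atlas sized like a real multi-timepoint reference (20 types,
        # 150 markers each) should give a signature in the low thousands of
        # genes after ortholog mapping
        spec = ad.AtlasSpec(n_cell_types=20, cells_per_type=40, n_genes=6000,
                            markers_per_type=150, marker_fold_change=8.0,
                            seed=17)
        counts, annot = ad.generate_reference_atlas(spec)
        norm = ad.normalize_log1p(counts)
        table = ad.wilcoxon_de_one_vs_rest(norm, annot["cluster"])
        orth = ad.generate_ortholog_map(counts.gene_ids, 0.9, seed=18)
        signature = ad.build_signature_matrix(norm, annot["cluster"], table,
                                              orthologs=orth)
        assert 1000 <= signature.shape[0] <= 6000

    def test_empty_universe_names_filter(self, small_normalized, small_labels):
        markers = ad.wilcoxon_de_one_vs_rest(small_normalized, small_labels)
        sets = ad.GeneExclusionSets(cell_cycle=frozenset(markers.gene))
        with pytest.raises(ad.ValidationError, match="exclusion"):
            ad.build_signature_matrix(
                small_normalized, small_labels, markers, exclusions=sets
            )


class TestSharedGenes:
    @pytest.fixture()
    def signature(self):
        return pd.DataFrame(
            {"emb": [2.0, 3.0, 0.1, 1.0, 4.0], "adult": [0.1] * 5},
            index=[f"g{i}" for i in range(5)],
        )

    def test_identical_profile_ranks_by_shared_level(self, signature):
        profile = signature["emb"].copy()
        out = ad.shared_signature_genes(signature, profile, "emb", top_n=5)
        assert (out["difference"] == 0).all()
        # all differences zero: highest shared expression first
        assert list(out.index) == ["g4", "g1", "g0", "g3"]  # g2 below floor

    def test_bruteforce_sort_order(self, signature):
        profile = pd.Series([2.5, 2.9, 5.0, 0.2, 4.1],
                            index=signature.index)
        out = ad.shared_signature_genes(signature, profile, "emb", top_n=5)
        floor = 0.5
        elig = [g for g in signature.index
                if profile[g] > floor and signature.loc[g, "emb"] > floor]
        expected = sorted(elig, key=lambda g: abs(profile[g] - signature.loc[g, "emb"]))
        assert list(out.index) == expected

    def test_absent_in_tumour_excluded_from_top(self, signature):
        profile = pd.Series([2.0, 0.0, 0.1, 1.0, 4.0], index=signature.index)
        out = ad.shared_signature_genes(signature, profile, "emb", top_n=5)
        assert "g1" not in out.index  # high in reference, absent in tumour

    def test_unknown_type_rejected(self, signature):
        with pytest.raises(ad.ValidationError, match="unknown"):
            ad.shared_signature_genes(signature, signature["emb"], "nosuch")
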