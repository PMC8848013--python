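"""Cross-model comparisons: Jaccard/clustering/ARI, variance decomposition,
rank shifts, correlation-class regression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from grnimpact import (
    RankedEdgeList,
    classify_edges,
    cluster_models,
    cluster_purity_ari,
    correlation_class_regression,
    harmonize_networks,
    jaccard_similarity,
    rank_shift,
    similarity_matrix,
    top_k,
    variance_by_factor,
)


class TestJaccard:
    def test_basic_values(self):
        assert jaccard_similarity({1, 2}, {1, 2}) == 1.0
        assert jaccard_similarity({1}, {2}) == 0.0
        assert jaccard_similarity(set(range(250)),
                                  set(range(750))) == pytest.approx(1 / 3)

    def test_empty_sets_flagged(self):
        with pytest.warns(UserWarning, match="empty"):
            assert jaccard_similarity(set(), set()) == 1.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            a = set(rng.integers(0, 20, size=rng.integers(1, 10)))
            b = set(rng.integers(0, 20, size=rng.integers(1, 10)))
            j = jaccard_similarity(a, b)
            assert 0.0 <= j <= 1.0
            assert j == jaccard_similarity(b, a)


class TestClustering:
    @staticmethod
    def _block_similarity():
        """Four models in two perfectly replicated groups."""
        groups = {"m1": {("a", "b")}, "m2": {("a", "b")},
                  "m3": {("c", "d")}, "m4": {("c", "d")}}
        return similarity_matrix(groups)

    def test_block_structure_recovered(self):
        labels = cluster_models(self._block_similarity(), 2)
        assert labels["m1"] == labels["m2"]
        assert labels["m3"] == labels["m4"]
        assert labels["m1"] != labels["m3"]

    def test_identical_models_stay_together(self):
        sim = similarity_matrix({f"m{i}": {("a", "b")} for i in range(4)})
        labels = cluster_models(sim, 2)
        assert labels.nunique() == 1

    def test_partition_invariant_to_model_order(self):
        sim = self._block_similarity()
        shuffled = sim.loc[["m3", "m1", "m4", "m2"], ["m3", "m1", "m4", "m2"]]
        a = cluster_models(sim, 2)
        b = cluster_models(shuffled, 2)
        assert cluster_purity_ari(a.tolist(), b.loc[a.index].tolist()) == 1.0

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_models(self._block_similarity(), 5)


class TestAri:
    def test_identical_partitions(self):
        assert cluster_purity_ari([1, 1, 2, 2], ["a", "a", "b", "b"]) == 1.0

    def test_singletons_vs_lump(self):
        assert cluster_purity_ari([1, 2, 3, 4], ["a", "a", "a", "a"]) == 0.0

    def test_random_labels_center_on_zero(self, rng):
        aris = [cluster_purity_ari(rng.integers(0, 3, 30).tolist(),
                                   rng.integers(0, 3, 30).tolist())
                for _ in range(1000)]
        assert abs(np.mean(aris)) < 0.02


def _grid(values):
    """Tidy metrics table from {(imp, grn): ratio}."""
    return pd.DataFrame([
        {"dataset": "d", "imputation": i, "grn_method": g,
         "log2_epr_ratio": v}
        for (i, g), v in values.items()])


class TestVarianceDecomposition:
    def test_constructed_contrast(self):
        """Ratios constant in imputation but varying in GRN: all variance
        sits across GRN methods."""
        imps, grns = ["i1", "i2", "i3"], ["g1", "g2", "g3"]
        effect = {"g1": 0.0, "g2": 1.0, "g3": 2.0}
        vd = variance_by_factor(_grid({(i, g): effect[g]
                                       for i in imps for g in grns}))
        assert (vd.var_across_imputation["variance"] == 0).all()
        assert (vd.var_across_grn["variance"] > 0).all()

    def test_all_equal_ratios(self):
        imps, grns = ["i1", "i2"], ["g1", "g2"]
        vd = variance_by_factor(_grid({(i, g): 0.5
                                       for i in imps for g in grns}))
        assert (vd.var_across_imputation["variance"] == 0).all()
        assert (vd.var_across_grn["variance"] == 0).all()
        assert vd.ranksum_p == 1.0

    def test_incomplete_grid_lists_missing_cells(self):
        df = _grid({("i1", "g1"): 0.1, ("i1", "g2"): 0.2, ("i2", "g1"): 0.3})
        with pytest.raises(ValueError, match="missing cells"):
            variance_by_factor(df)

    def test_dominant_factor_recovered(self):
        """Injected imputation effect 4x the GRN effect: the ANOVA puts the
        smaller p-value on imputation in nearly all seeds."""
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            imps = [f"i{k}" for k in range(5)]
            grns = [f"g{k}" for k in range(4)]
            a = dict(zip(imps, rng.normal(0, 0.8, len(imps))))
            b = dict(zip(grns, rng.normal(0, 0.2, len(grns))))
            vd = variance_by_factor(_grid({
                (i, g): a[i] + b[g] + rng.normal(0, 0.1)
                for i, g in itertools.product(imps, grns)}))
            tbl = vd.anova_tables["d"]
            wins += (tbl.loc["C(imputation)", "PR(>F)"]
                     < tbl.loc["C(grn_method)", "PR(>F)"])
        assert wins >= 0.95 * n_seeds


class TestRankShift:
    def test_identical_rankings_shift_zero(self):
        ranked = RankedEdgeList.from_records(
            [("t", f"g{i}", 10.0 - i) for i in range(5)])
        tp = {("t", "g0"), ("t", "g2")}
        out = rank_shift(tp, ranked, ranking_unimputed=ranked)
        assert (out["shift"] == 0).all()

    def test_reversed_ranking(self):
        before = RankedEdgeList.from_records(
            [("t", f"g{i}", 10.0 - i) for i in range(10)])
        after = RankedEdgeList.from_records(
            [("t", f"g{i}", float(i)) for i in range(10)])
        out = rank_shift({("t", "g0")}, after, ranking_unimputed=before)
        assert out.loc[0, "rank_before"] == 1
        assert out.loc[0, "rank_after"] == 10

    def test_missing_edge_gets_sentinel_rank(self):
        after = RankedEdgeList.from_records([("t", "g1", 1.0)])
        out = rank_shift({("t", "gX")}, after, universe_size=40)
        assert out.loc[0, "rank_after"] == 41
        assert bool(out.loc[0, "missing_after"])

    def test_median_shift_matches_bruteforce(self, rng):
        """Median shift equals a naive recomputation on a 20-edge toy."""
        edges = [("t", f"g{i}") for i in range(20)]
        w_before = rng.permutation(20).astype(float)
        w_after = rng.permutation(20).astype(float)
        before = RankedEdgeList.from_records(
            [(s, t, w) for (s, t), w in zip(edges, w_before)])
        after = RankedEdgeList.from_records(
            [(s, t, w) for (s, t), w in zip(edges, w_after)])
        tp = set(edges[:8])
        out = rank_shift(tp, after, ranking_unimputed=before)
        naive = []
        for s, t in tp:
            rb = 1 + sum(w_before[edges.index((s, t))] < w for w in w_before)
            ra = 1 + sum(w_after[edges.index((s, t))] < w for w in w_after)
            naive.append(ra - rb)
        assert np.median(out["shift"]) == np.median(naive)


class TestCorrelationClassRegression:
    def test_identity_imputation_gives_unit_line(self, small_normalized,
                                                 small_truth, small_selection):
        from grnimpact import infer_partial_correlation

        pred = infer_partial_correlation(small_normalized, small_selection)
        pred_h, ref_h = harmonize_networks(pred, small_truth, small_selection)
        cls = classify_edges(top_k(pred_h, ref_h.n_edges), ref_h)
        table = correlation_class_regression(small_normalized,
                                             small_normalized, cls)
        for _, row in table.lines.dropna().iterrows():
            assert row["slope"] == pytest.approx(1.0, abs=1e-9)
            assert row["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_class_flagged(self, small_normalized):
        from grnimpact import EdgeClassification

        g = small_normalized.gene_ids
        cls = EdgeClassification(tp=frozenset({(g[0], g[1])}),
                                 fp=frozenset(), fn=frozenset(), n_reported=1)
        table = correlation_class_regression(small_normalized,
                                             small_normalized, cls)
        assert np.isnan(table.lines.loc["FP", "slope"])
        assert table.lines.loc["TP", "n"] == 1

    def test_constant_gene_excluded(self, small_normalized):
        from grnimpact import EdgeClassification, ExpressionDataset

        counts = small_normalized.counts.copy()
        counts[0] = 1.0
        flat = ExpressionDataset(counts, small_normalized.gene_ids,
                                 small_normalized.tf_flags,
                                 small_normalized.pseudotime,
                                 layer_tag="normalized")
        g = small_normalized.gene_ids
        cls = EdgeClassification(tp=frozenset({(g[0], g[1])}),
                                 fp=frozenset(), fn=frozenset(), n_reported=1)
        table = correlation_class_regression(flat, flat, cls)
        assert len(table.table) == 0
        assert table.excluded
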