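"""Edge scoring: tree importances, boosting, MI, partial correlation, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from grnimpact import (
    ExpressionDataset,
    SimulationConfig,
    competition_ranks,
    evaluate_model,
    infer_boosted,
    infer_mi_context,
    infer_partial_correlation,
    infer_tree_importance,
    jaccard_similarity,
    load_external_ranked_edges,
    mi_bits,
    normalize,
    sample_ground_truth,
    simulate_counts,
)


def _toy_dataset(rng, n_tfs=4, n_targets=6, n_cells=100, copy_tf=None):
    """TFs are noise; optionally one target copies a TF exactly."""
    n_genes = n_tfs + n_targets
    counts = rng.random((n_genes, n_cells)) * 5
    gene_ids = [f"TF{i}" for i in range(n_tfs)] + [f"G{i}" for i in range(n_targets)]
    if copy_tf is not None:
        counts[n_tfs] = counts[copy_tf]
    flags = np.array([True] * n_tfs + [False] * n_targets)
    return ExpressionDataset(counts, gene_ids, flags,
                             np.linspace(0, 1, n_cells), layer_tag="normalized")


class TestCompetitionRanking:
    def test_documented_tie_example(self):
        np.testing.assert_array_equal(
            competition_ranks([5.0, 4.0, 4.0, 3.0]), [1, 2, 2, 4])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=-5, max_value=5),
                    min_size=1, max_size=30))
    def test_rank_properties(self, weights):
        ranks = competition_ranks(np.array(weights, dtype=float))
        assert ranks.min() == 1
        assert ranks.max() <= len(weights)
        order = np.argsort(-np.array(weights, dtype=float))
        # larger weight never gets a worse (larger) rank
        assert all(ranks[order[i]] <= ranks[order[i + 1]]
                   for i in range(len(order) - 1))

    def test_ranks_invariant_to_row_order(self, rng):
        data = _toy_dataset(rng)
        ranked = infer_mi_context(data)
        perm = ranked.edges.sample(frac=1.0, random_state=1)
        from grnimpact import RankedEdgeList

        reranked = RankedEdgeList(perm[["source", "target", "weight"]])
        assert reranked.rank_of() == ranked.rank_of()


class TestTreeImportance:
    def test_perfect_predictor_ranked_first(self, rng):
        data = _toy_dataset(rng, copy_tf=1)
        ranked = infer_tree_importance(data, n_trees=30, seed=0)
        g0 = ranked.edges[ranked.edges["target"] == "G0"]
        best = g0.loc[g0["weight"].idxmax(), "source"]
        assert best == "TF1"

    def test_constant_target_scores_zero(self, rng):
        data = _toy_dataset(rng)
        counts = data.counts.copy()
        counts[5] = 2.0
        data2 = ExpressionDataset(counts, data.gene_ids, data.tf_flags,
                                  data.pseudotime, layer_tag="normalized")
        ranked = infer_tree_importance(data2, n_trees=20, seed=0)
        g1 = ranked.edges[ranked.edges["target"] == "G1"]
        assert (g1["weight"] == 0).all()

    def test_recovers_simulated_network_above_chance(self):
        """EPR beats the random-predictor level of 1 across seeds
        (one-sided Wilcoxon)."""
        eprs = []
        for seed in range(10):
            cfg = SimulationConfig(n_tfs=10, n_genes=60, n_cells=120,
                                   effect_size=2.0, seed=seed)
            net = sample_ground_truth(cfg)
            norm = normalize(simulate_counts(net, cfg))
            ranked = infer_tree_importance(norm, n_trees=25, seed=seed)
            eprs.append(evaluate_model(ranked, net).epr)
        assert stats.wilcoxon(np.array(eprs) - 1.0,
                              alternative="greater").pvalue < 0.01


class TestBoosted:
    def test_perfect_predictor_and_determinism(self, rng):
        data = _toy_dataset(rng, copy_tf=2)
        a = infer_boosted(data, n_rounds=30, seed=3)
        b = infer_boosted(data, n_rounds=30, seed=3)
        pd.testing.assert_frame_equal(a.edges, b.edges)
        g0 = a.edges[a.edges["target"] == "G0"]
        assert g0.loc[g0["weight"].idxmax(), "source"] == "TF2"

    def test_family_coherence_with_forest(self, small_normalized,
                                          small_selection, rng):
        """Boosted and forest rankings agree far beyond a random edge set of
        the same size."""
        boost = infer_boosted(small_normalized, small_selection,
                              n_rounds=30, seed=1)
        tree = infer_tree_importance(small_normalized, small_selection,
                                     n_trees=25, seed=1)
        top = 200
        eb = set(map(tuple, boost.edges.nlargest(top, "weight")
                     [["source", "target"]].itertuples(index=False)))
        et = set(map(tuple, tree.edges.nlargest(top, "weight")
                     [["source", "target"]].itertuples(index=False)))
        universe = list(map(tuple, tree.edges[["source", "target"]]
                            .itertuples(index=False)))
        random_edges = {universe[i] for i in
                        rng.choice(len(universe), size=top, replace=False)}
        assert jaccard_similarity(eb, et) > jaccard_similarity(eb, random_edges)


class TestMutualInformation:
    def test_identity_channel_is_log2_bins(self, rng):
        x = rng.normal(size=4000)
        assert mi_bits(x, x, n_bins=8) == pytest.approx(3.0, abs=1e-9)

    def test_invariant_under_monotone_maps(self, rng):
        x = rng.normal(size=1000)
        assert mi_bits(x, -x) == pytest.approx(mi_bits(x, x), abs=1e-12)
        assert mi_bits(x, np.exp(x)) == pytest.approx(mi_bits(x, x), abs=1e-12)

    def test_independent_genes_within_permutation_null(self, rng):
        """Finite-sample MI of independent genes is positively biased but
        stays below the 95th percentile of its own permutation null."""
        x, y = rng.uniform(size=2000), rng.uniform(size=2000)
        observed = mi_bits(x, y)
        null = np.array([mi_bits(x, rng.permutation(y)) for _ in range(200)])
        assert observed < np.quantile(null, 0.95)
        assert observed < 0.05  # small in absolute terms as n grows

    def test_undirected_pairs_share_rank(self, rng):
        ranked = infer_mi_context(_toy_dataset(rng))
        rank = ranked.rank_of()
        for (s, t), r in rank.items():
            assert rank[(t, s)] == r


class TestPartialCorrelation:
    def test_chain_shortcut_suppressed(self, rng):
        """X -> Y -> Z Gaussian chain: corr(X, Z) is strong but the partial
        correlation given Y vanishes, so only the chain edges survive."""
        n = 4000
        x = rng.normal(size=n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        z = 0.9 * y + np.sqrt(1 - 0.81) * rng.normal(size=n)
        assert abs(np.corrcoef(x, z)[0, 1]) > 0.5
        data = ExpressionDataset(
            np.abs(np.vstack([x, y, z])) , ["X", "Y", "Z"],
            np.array([True, True, True]), np.linspace(0, 1, n),
            layer_tag="normalized")
        ranked = infer_partial_correlation(data, threshold=0.1)
        edges = ranked.edge_set()
        assert ("X", "Y") in edges and ("Y", "Z") in edges
        assert ("X", "Z") not in edges

    def test_threshold_is_strict(self, small_normalized, small_selection):
        full = infer_partial_correlation(small_normalized, small_selection,
                                         threshold=0.0)
        w = float(full.edges["weight"].iloc[len(full) // 2])
        cut = infer_partial_correlation(small_normalized, small_selection,
                                        threshold=w)
        assert len(cut) < len(full)
        assert (cut.edges["weight"] > w).all()

    def test_independent_genes_yield_sparse_list(self, rng):
        data = _toy_dataset(rng, n_tfs=4, n_targets=8, n_cells=3000)
        ranked = infer_partial_correlation(data, threshold=0.1)
        assert len(ranked) == 0

    def test_singular_covariance_without_shrinkage(self, rng):
        counts = rng.random((30, 10))  # more genes than cells
        data = ExpressionDataset(counts, [f"TF{i}" for i in range(30)],
                                 np.ones(30, bool), np.linspace(0, 1, 10),
                                 layer_tag="normalized")
        with pytest.raises(np.linalg.LinAlgError, match="shrink"):
            infer_partial_correlation(data, shrink=False)


class TestExternalRankedEdges:
    def test_competition_ranks_recomputed(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("Gene1\tGene2\tEdgeWeight\n"
                        "a\tb\t5\na\tc\t4\nb\tc\t4\nc\td\t3\n")
        ranked = load_external_ranked_edges(path)
        assert ranked.edges["rank"].tolist() == [1, 2, 2, 4]

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("Gene1\tGene2\tEdgeWeight\n")
        with pytest.warns(UserWarning, match="empty"):
            ranked = load_external_ranked_edges(path)
        assert len(ranked) == 0

    def test_duplicate_rows_rejected_with_line_numbers(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("Gene1\tGene2\tEdgeWeight\na\tb\t5\na\tb\t4\n")
        with pytest.raises(ValueError, match="line"):
            load_external_ranked_edges(path)

    def test_bad_weight_rejected_with_line_numbers(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("Gene1\tGene2\tEdgeWeight\na\tb\tfoo\n")
        with pytest.raises(ValueError, match="line"):
            load_external_ranked_edges(path)
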