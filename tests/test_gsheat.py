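import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import gscontrast as gc


def _sheet(n_a: int, n_b: int) -> gc.SampleSheet:
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return gc.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ids,
                "age_group": ["young"] * (n_a + n_b),
                "treatment": ["sham"] * n_a + ["DOCA"] * n_b,
            }
        )
    )


class TestRanks:
    def test_worked_example_ordering(self, toy_counts):
        ranks = gc.rank_within_sample(toy_counts)
        np.testing.assert_array_equal(ranks[:, 0], [3, 1, 4, 2])

    def test_average_tie_policy(self):
        cm = gc.CountMatrix(["a", "b", "c"], ["s1", "s2"], np.array([[2, 1], [2, 2], [5, 3]]))
        ranks = gc.rank_within_sample(cm)
        np.testing.assert_array_equal(ranks[:, 0], [1.5, 1.5, 3])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.int64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=25),
            elements=st.integers(0, 1000),
        )
    )
    def test_rank_sum_conservation(self, counts):
        cm = gc.CountMatrix(
            [f"g{i}" for i in range(counts.shape[0])],
            [f"s{j}" for j in range(counts.shape[1])],
            counts,
        )
        ranks = gc.rank_within_sample(cm)
        n = cm.n_genes
        np.testing.assert_allclose(ranks.sum(axis=0), n * (n + 1) / 2)


class TestSetScores:
    def test_worked_example_score(self, toy_counts):
        col = gc.GeneSetCollection({"S": ["gA", "gC"]})
        scores = gc.set_score_matrix(toy_counts, col)
        assert scores.to_frame().loc["S", "s1"] == 7  # ranks 3 + 4

    def test_universe_set_is_constant(self, toy_counts):
        col = gc.GeneSetCollection({"ALL": ["gA", "gB", "gC", "gD"]})
        scores = gc.set_score_matrix(toy_counts, col)
        np.testing.assert_allclose(scores.to_frame().loc["ALL"], 10.0)

    def test_invariance_under_monotone_transform(self, sim_dataset):
        counts = sim_dataset["counts"]
        col = sim_dataset["collection"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = gc.set_score_matrix(counts, col)
            scaled = gc.set_score_matrix(
                gc.CountMatrix(counts.gene_ids, counts.sample_ids, counts.counts * 10),
                col,
            )
        np.testing.assert_array_equal(raw.scores, scaled.scores)

    def test_partition_conservation(self):
        rng = np.random.default_rng(3)
        n = 40
        cm = gc.CountMatrix(
            [f"g{i}" for i in range(n)],
            ["s1", "s2", "s3"],
            rng.integers(0, 500, size=(n, 3)),
        )
        parts = {"P1": [f"g{i}" for i in range(15)],
                 "P2": [f"g{i}" for i in range(15, 30)],
                 "P3": [f"g{i}" for i in range(30, 40)]}
        scores = gc.set_score_matrix(cm, gc.GeneSetCollection(parts))
        np.testing.assert_allclose(scores.scores.sum(axis=0), n * (n + 1) / 2)

    def test_monotonicity_in_member_counts(self, toy_counts):
        col = gc.GeneSetCollection({"S": ["gA", "gB"]})
        before = gc.set_score_matrix(toy_counts, col).to_frame().loc["S", "s1"]
        boosted = toy_counts.counts.copy()
        boosted[0] += 100  # raise gA everywhere
        after = gc.set_score_matrix(
            gc.CountMatrix(toy_counts.gene_ids, toy_counts.sample_ids, boosted), col
        ).to_frame().loc["S", "s1"]
        assert after >= before

    def test_score_bounds(self, sim_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = gc.set_score_matrix(sim_dataset["counts"], sim_dataset["collection"])
        n = scores.n_genes
        for i, name in enumerate(scores.set_names):
            k = scores.member_count_used[name]
            assert (scores.scores[i] >= k * (k + 1) / 2).all()
            assert (scores.scores[i] <= k * (2 * n - k + 1) / 2).all()

    def test_no_surviving_set_errors(self, toy_counts):
        col = gc.GeneSetCollection({"S": ["nope1", "nope2"]})
        with pytest.raises(ValueError, match="no gene set"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gc.set_score_matrix(toy_counts, col)


class TestDifferentialSets:
    def test_identical_groups_are_null(self):
        scores = gc.SetScoreMatrix(
            ["S1"], [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
            np.array([[10.0, 12.0, 14.0, 10.0, 12.0, 14.0]]),
            {"S1": 3}, 20,
        )
        res = gc.differential_sets(scores, _sheet(3, 3), "young-sham", "young-DOCA")
        assert res.table["t_moderated"].iloc[0] == pytest.approx(0.0)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_ordinary_t_matches_textbook(self):
        """Pooled-variance t from an independent implementation, 100 instances."""
        from scipy import stats as ss

        rng = np.random.default_rng(17)
        n_a, n_b = 5, 7
        mat = rng.normal(50, 10, size=(100, n_a + n_b))
        scores = gc.SetScoreMatrix(
            [f"S{i}" for i in range(100)],
            [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)],
            mat, {f"S{i}": 5 for i in range(100)}, 1000,
        )
        res = gc.differential_sets(
            scores, _sheet(n_a, n_b), "young-sham", "young-DOCA", method="ordinary_t"
        )
        t_ref, p_ref = ss.ttest_ind(mat[:, n_a:], mat[:, :n_a], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t_moderated"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res.table["p"], p_ref, rtol=1e-10)

    def test_moderated_t_null_calibration(self):
        cfg = gc.SimulationConfig(seed=42, de_fraction=0, n_active_sets=0)
        counts, sheet, _ = gc.simulate_counts(cfg)
        universe = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
        col = gc.simulate_random_collection(500, (10, 50), universe, seed=43)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = gc.set_score_matrix(counts, col)
        res = gc.differential_sets(scores, sheet, "young-sham", "young-DOCA")
        frac = (res.table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_activated_set_detected(self, sim_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = gc.set_score_matrix(sim_dataset["counts"], sim_dataset["collection"])
        res = gc.differential_sets(
            scores, sim_dataset["sheet"], "young-sham", "young-DOCA"
        )
        for name, direction in sim_dataset["truth"].active_sets["young"].items():
            assert res.table.loc[name, "fdr"] < 0.05
            assert np.sign(res.table.loc[name, "t_moderated"]) == direction

    def test_single_sample_group_rejected(self):
        scores = gc.SetScoreMatrix(
            ["S"], ["a0", "b0", "b1"], np.array([[1.0, 2.0, 3.0]]), {"S": 2}, 5
        )
        with pytest.raises(ValueError, match=">= 2"):
            gc.differential_sets(scores, _sheet(1, 2), "young-sham", "young-DOCA")


class TestHeatmapAndMap:
    def _scores_and_diff(self, mat, n_a=3, n_b=3, n_genes=50):
        names = [f"S{i}" for i in range(mat.shape[0])]
        scores = gc.SetScoreMatrix(
            names,
            [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)],
            mat.astype(float), {n: 5 for n in names}, n_genes,
        )
        diff = gc.differential_sets(scores, _sheet(n_a, n_b), "young-sham", "young-DOCA")
        return scores, diff

    def test_all_sets_requested_returns_all(self):
        rng = np.random.default_rng(4)
        scores, diff = self._scores_and_diff(rng.normal(40, 5, size=(12, 6)))
        ordered = gc.top_sets_heatmap(scores, diff, n_top=12)
        assert set(ordered.index) == set(scores.set_names)
        with pytest.raises(ValueError):
            gc.top_sets_heatmap(scores, diff, n_top=13)

    def test_constant_row_z_scores_zero(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(40, 5, size=(10, 6))
        mat[0] = 33.0
        scores, diff = self._scores_and_diff(mat)
        ordered = gc.top_sets_heatmap(scores, diff, n_top=10)
        np.testing.assert_allclose(ordered.loc["S0"], 0.0)

    def test_duplicated_samples_cluster_together(self, tmp_path):
        rng = np.random.default_rng(6)
        mat = rng.normal(40, 8, size=(15, 6))
        mat[:, 3] = mat[:, 0]  # duplicate: column b0 equals column a0
        scores, diff = self._scores_and_diff(mat)
        ordered = gc.top_sets_heatmap(
            scores, diff, n_top=15, figure_path=tmp_path / "hm.svg"
        )
        cols = list(ordered.columns)
        assert abs(cols.index("a0") - cols.index("b0")) == 1
        assert (tmp_path / "hm.svg").exists()

    def test_enrichment_map_exports(self, tmp_path):
        table = pd.DataFrame(
            {
                "mean_a": [1, 1, 1],
                "mean_b": [2, 2, 2],
                "t_moderated": [3.0, -2.5, 4.0],
                "p": [0.001, 0.002, 0.003],
                "fdr": [0.01, 0.02, 0.03],
            },
            index=pd.Index(["X", "Y", "Z"], name="set_name"),
        )
        diff = gc.DifferentialSetResult("a", "b", "moderated_t", table)
        disjoint = gc.GeneSetCollection({"X": ["g1", "g2"], "Y": ["g3", "g4"], "Z": ["g5", "g6"]})
        nodes, edges = gc.export_enrichment_map(diff, disjoint)
        assert len(nodes) == 3 and len(edges) == 0
        assert set(nodes["direction"]) == {"up", "down"}

        identical = gc.GeneSetCollection(
            {"X": ["g1", "g2"], "Y": ["g1", "g2"], "Z": ["q1", "q2"]}
        )
        _, edges = gc.export_enrichment_map(diff, identical)
        assert len(edges) == 1 and edges["jaccard"].iloc[0] == pytest.approx(1.0)

        nested = gc.GeneSetCollection(
            {
                "X": [f"g{i}" for i in range(10)],
                "Y": [f"g{i}" for i in range(20)],
                "Z": [f"q{i}" for i in range(5)],
            }
        )
        _, edges = gc.export_enrichment_map(
            diff, nested, node_path=tmp_path / "n.tsv", edge_path=tmp_path / "e.tsv"
        )
        assert edges["jaccard"].iloc[0] == pytest.approx(0.5)
        assert (tmp_path / "n.tsv").exists() and (tmp_path / "e.tsv").exists()
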