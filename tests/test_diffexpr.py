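import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gscontrast as gc
from gscontrast.diffexpr import exact_nb_pvalue


def _matrix(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows))
    genes = [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return gc.CountMatrix(genes, samples, rows)


class TestFilterLowCounts:
    def test_boundary_mean_exactly_ten_retained(self):
        cm = _matrix([[9, 10, 11], [0, 0, 29]])
        out = gc.filter_low_counts(cm)
        assert out.gene_ids == ["g0"]  # mean 10 kept, mean 9.67 dropped

    def test_all_zero_matrix_warns_and_empties(self):
        with pytest.warns(UserWarning, match="every gene"):
            out = gc.filter_low_counts(_matrix(np.zeros((3, 2), dtype=int)))
        assert out.n_genes == 0

    def test_idempotent(self, sim_dataset):
        once = gc.filter_low_counts(sim_dataset["counts"])
        twice = gc.filter_low_counts(once)
        assert once.gene_ids == twice.gene_ids


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        col = np.array([5, 20, 100, 7])
        cm = _matrix(np.column_stack([col, col]))
        f = gc.tmm_factors(cm)
        np.testing.assert_allclose(f.scale_factors, [1.0, 1.0])

    def test_scale_invariance_doubled_sample(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, size=200)
        cm = _matrix(np.column_stack([col, 2 * col]))
        f = gc.tmm_factors(cm)
        np.testing.assert_allclose(f.scale_factors, [1.0, 1.0], atol=1e-12)

    def test_matches_brute_force_trimmed_mean(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 400, size=300)
        inflated = base.copy()
        inflated[0] *= 60  # one dominant transcript in sample 2
        cm = _matrix(np.column_stack([base, inflated]))
        f = gc.tmm_factors(cm)

        # independent straightforward computation against sample 1 as ref
        n1, n2 = base.sum(), inflated.sum()
        m = np.log2((inflated / n2) / (base / n1))
        a = 0.5 * np.log2((inflated / n2) * (base / n1))
        lo_m, hi_m = np.quantile(m, [0.3, 0.7])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        expected = 2 ** m[keep].mean()
        ratio = f.scale_factors[1] / f.scale_factors[0]
        assert ratio == pytest.approx(expected, rel=0.02)

    def test_zero_sample_named(self):
        cm = _matrix(np.array([[1, 0], [2, 0]]), samples=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            gc.tmm_factors(cm)

    def test_geometric_mean_one(self, sim_dataset):
        f = gc.tmm_factors(sim_dataset["counts"])
        assert np.exp(np.mean(np.log(f.scale_factors))) == pytest.approx(1.0)
        assert (f.scale_factors > 0).all()


class TestExactTest:
    def test_zero_dispersion_reduces_to_conditional_binomial(self):
        # 0 vs 10 in a forced 1-vs-1 split: two-sided p = 2 * (1/2)^10
        p = exact_nb_pvalue(0, 10, 1, 1, dispersion=0.0)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_identical_group_counts_are_null(self):
        rows = np.tile([40, 41, 39, 40, 41, 39, 40, 40], (30, 1))
        rows = rows + np.arange(30)[:, None]  # distinct genes, same in both groups
        cm = _matrix(rows)
        sheet = gc.SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": [f"s{j}" for j in range(8)],
                    "age_group": ["young"] * 8,
                    "treatment": ["sham"] * 4 + ["DOCA"] * 4,
                }
            )
        )
        res = gc.nb_exact_contrast(cm, sheet, "young-sham", "young-DOCA")
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-9)
        np.testing.assert_allclose(res.table["p_value"], 1.0)

    def test_missing_group_raises(self, toy_counts):
        sheet = gc.SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2"],
                    "age_group": ["young", "young"],
                    "treatment": ["sham", "sham"],
                }
            )
        )
        with pytest.raises(ValueError):
            gc.nb_exact_contrast(toy_counts, sheet, "young-sham", "young-DOCA")

    def test_relabeling_within_group_invariance(self):
        cfg = gc.SimulationConfig(seed=31, n_genes=300)
        counts, sheet, _ = gc.simulate_counts(cfg)
        filtered = gc.filter_low_counts(counts)
        res = gc.nb_exact_contrast(filtered, sheet, "young-sham", "young-DOCA")
        shuffled = sheet.table.copy()
        young_sham = shuffled["sample_id"].iloc[:6].tolist()
        # swap two sample rows within the same group
        order = [1, 0] + list(range(2, len(shuffled)))
        res2 = gc.nb_exact_contrast(
            filtered, gc.SampleSheet(shuffled.iloc[order]), "young-sham", "young-DOCA"
        )
        np.testing.assert_allclose(res.table["p_value"], res2.table["p_value"])

    def test_null_rejection_rate_close_to_nominal(self):
        cfg = gc.SimulationConfig(seed=105, de_fraction=0.0, n_active_sets=0)
        counts, sheet, _ = gc.simulate_counts(cfg)
        filtered = gc.filter_low_counts(counts)
        res = gc.nb_exact_contrast(filtered, sheet, "young-sham", "young-DOCA")
        frac = (res.table["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestRanking:
    @pytest.mark.parametrize(
        "lfc,p,expected",
        [(1.5, 0.02, 50.0), (-0.5, 0.5, -2.0), (0.0, 0.9, 0.0)],
    )
    def test_signed_inverse_p_examples(self, lfc, p, expected):
        out = gc.signed_inverse_p_rank(np.array([lfc]), np.array([p]))
        assert out[0] == pytest.approx(expected)

    def test_zero_p_clamped_finite(self):
        out = gc.signed_inverse_p_rank(np.array([1.0, -1.0]), np.array([0.0, 1e-10]))
        assert np.isfinite(out).all() and out[0] > 0 > out[1]

    def test_rank_score_orders_most_upregulated_first(self, sim_contrasts):
        ranked = sim_contrasts["young"].ranked_gene_list()
        scores = ranked.to_numpy()
        assert (np.diff(scores) <= 0).all()
        t = sim_contrasts["young"].table
        up = t[t["log2fc"] > 0]
        # the most significant up-regulated gene carries the largest score
        assert ranked.index[0] == up["p_value"].idxmin()


class TestBH:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            gc.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_degenerate_inputs(self):
        assert gc.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(gc.bh_adjust(np.ones(5)), np.ones(5))
        with pytest.raises(ValueError):
            gc.bh_adjust(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, ps):
        p = np.array(ps)
        q = gc.bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        for rank_i, idx in enumerate(order, start=1):
            candidates = [
                p[order[j]] * m / (j + 1) for j in range(rank_i - 1, m)
            ]
            expected[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestCompareContrasts:
    def test_identity_comparison(self, sim_contrasts):
        res = sim_contrasts["young"]
        cmp = gc.compare_contrasts(res, res)
        n_sig = (res.table["fdr"] < 0.05).sum()
        assert cmp["shared"] == n_sig
        assert cmp["unique_a"] == cmp["unique_b"] == 0
        assert cmp["spearman"] == pytest.approx(1.0)

    def test_sign_flip_antisymmetry(self, sim_contrasts):
        res = sim_contrasts["young"]
        flipped = gc.ContrastResult(
            res.group_a, res.group_b, res.table.assign(rank_score=-res.table["rank_score"])
        )
        cmp = gc.compare_contrasts(res, flipped)
        assert cmp["spearman"] == pytest.approx(-1.0)

    def test_disjoint_universes_error(self, sim_contrasts):
        other = gc.ContrastResult(
            "a", "b", sim_contrasts["young"].table.rename(index=lambda g: "x" + g)
        )
        with pytest.raises(ValueError, match="share no genes"):
            gc.compare_contrasts(sim_contrasts["young"], other)

    def test_planted_overlap_recovered(self):
        """Two strata sharing half their planted DE genes yield a shared
        Venn count near the planted overlap."""
        cfg = gc.SimulationConfig(seed=51, de_fraction=0.0, n_active_sets=0)
        counts, sheet, _ = gc.simulate_counts(cfg)
        rng = np.random.default_rng(52)
        planted = rng.choice(cfg.n_genes, size=120, replace=False)
        shared, only_a, only_b = planted[:40], planted[40:80], planted[80:]
        y = counts.counts.astype(float)
        doca_young = [i for i, s in enumerate(counts.sample_ids) if "young-DOCA" in s]
        doca_aging = [i for i, s in enumerate(counts.sample_ids) if "aging-DOCA" in s]
        for rows, cols in (
            (np.concatenate([shared, only_a]), doca_young),
            (np.concatenate([shared, only_b]), doca_aging),
        ):
            y[np.ix_(rows, cols)] *= 16  # 4 log2 units
        boosted = gc.CountMatrix(counts.gene_ids, counts.sample_ids, np.rint(y))
        filtered = gc.filter_low_counts(boosted)
        ra = gc.nb_exact_contrast(filtered, sheet, "young-sham", "young-DOCA")
        rb = gc.nb_exact_contrast(filtered, sheet, "aging-sham", "aging-DOCA")
        cmp = gc.compare_contrasts(ra, rb)
        planted_shared_present = sum(
            counts.gene_ids[i] in ra.table.index for i in shared
        )
        assert cmp["shared"] == pytest.approx(planted_shared_present, rel=0.2)


def test_pca_coordinates_shape(sim_contrasts):
    coords = gc.pca_coordinates(sim_contrasts["filtered"])
    assert coords.shape == (18, 2)
    assert coords.attrs["explained_fraction"][0] > 0
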