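import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hypothesis import given, settings
from hypothesis import strategies as st

from secretodiff import (bh_adjust, call_hits, overlap_summary,
                         fit_contrasts, welch_test)

from conftest import make_design, make_matrix


def brute_force_bh(p):
    """Independent step-up oracle: q(i) = min_{j>=i} p(j)*m/j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestWelch:
    def test_hand_evaluated_example(self):
        t, df, p = welch_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
        assert df == pytest.approx(4.0, rel=1e-12)
        # independent p oracle from the t CDF at the hand-derived statistic
        assert p == pytest.approx(2 * stats.t.cdf(-3 / np.sqrt(2 / 3), 4), rel=1e-12)

    def test_identical_groups_give_t0_p1(self):
        t, df, p = welch_test([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert t == 0.0
        assert p == 1.0

    def test_unequal_variances_shrink_df_below_pooled(self):
        t, df, p = welch_test([0.0, 10.0], [5.0, 5.1])
        assert df < 2 + 2 - 2 + 1e-9
        # Welch-Satterthwaite evaluated directly
        vx, vy = np.var([0, 10.0], ddof=1), np.var([5, 5.1], ddof=1)
        expected_df = (vx / 2 + vy / 2) ** 2 / (
            (vx / 2) ** 2 / 1 + (vy / 2) ** 2 / 1)
        assert df == pytest.approx(expected_df, rel=1e-9)

    def test_zero_variance_different_means_keeps_direction(self):
        t, df, p = welch_test([5.0, 5.0], [3.0, 3.0])
        assert t > 0
        assert np.isfinite(p) and p < 0.05

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2,
                    max_size=8),
           st.lists(st.floats(min_value=-50, max_value=50), min_size=2,
                    max_size=8))
    def test_swapping_groups_flips_t_preserves_df_and_p(self, x, y):
        t1, df1, p1 = welch_test(x, y)
        t2, df2, p2 = welch_test(y, x)
        assert t1 == pytest.approx(-t2, abs=1e-9)
        assert df1 == pytest.approx(df2, rel=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_rejects_single_value_groups(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestBH:
    def test_worked_examples(self):
        assert bh_adjust([0.005, 0.04, 0.05]) == pytest.approx([0.015, 0.05, 0.05])
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            if rng.random() < 0.3:  # inject ties
                p[rng.integers(m)] = p[rng.integers(m)]
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p),
                                       rtol=1e-10, atol=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_brute_force_equivalence_property(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p),
                                   rtol=1e-10, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_q_at_least_p_and_order_invariant(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], rtol=1e-12)


class TestHitCalling:
    @pytest.mark.parametrize("q, lfc, hit", [
        (0.1, 2.0, False),    # FDR threshold is strict
        (0.09, 1.0, True),    # |log2FC| threshold is inclusive
        (0.05, 0.99, False),
        (0.05, -1.2, True),
    ])
    def test_thresholds(self, q, lfc, hit):
        res = pd.DataFrame({"q": [q], "log2fc": [lfc]})
        assert call_hits(res)["hit"].iloc[0] == hit


class TestContrasts:
    def _matrix(self, rng):
        design = make_design({"UT": 4, "T1": 4, "T2": 4})
        vals = rng.normal(0, 0.3, size=(30, 12))
        vals[0, 4:8] += 3.0  # strong planted effect in T1
        m = make_matrix({f"P{i:02d}": vals[i] for i in range(30)}, design,
                        stage="imputed")
        return design, m

    def test_planted_effect_is_top_hit_with_consistent_sign(self, rng):
        design, m = self._matrix(rng)
        res = fit_contrasts(m, design)
        r0 = res[(res["protein_id"] == "P00") & (res["contrast"] == "T1_vs_UT")]
        assert r0["hit"].iloc[0]
        assert r0["log2fc"].iloc[0] > 2
        assert np.sign(res["log2fc"]).equals(np.sign(res["t_stat"]))

    def test_q_within_family_invariant_to_protein_order(self, rng):
        design, m = self._matrix(rng)
        res = fit_contrasts(m, design).set_index(["protein_id", "contrast"])
        shuffled = m.select_proteins(list(rng.permutation(m.protein_ids)))
        res2 = fit_contrasts(shuffled, design).set_index(["protein_id", "contrast"])
        pd.testing.assert_series_equal(res["q"], res2["q"].loc[res.index])

    def test_family_is_per_batch_contrast_pair(self, rng):
        design, m = self._matrix(rng)
        res = fit_contrasts(m, design, family="per_contrast")
        for _, grp in res.groupby(["batch", "contrast"]):
            np.testing.assert_allclose(
                grp["q"].to_numpy(), bh_adjust(grp["p"].to_numpy()), rtol=1e-12)

    def test_requires_imputed_matrix(self, rng):
        design = make_design({"UT": 2, "T": 2})
        m = make_matrix({"A": [1.0, np.nan, 2.0, 3.0]}, design, stage="imputed")
        with pytest.raises(ValueError, match="imputed"):
            fit_contrasts(m, design)


class TestOverlap:
    def _results(self, hits_by_batch):
        rows = []
        for batch, pids in hits_by_batch.items():
            for pid in pids:
                rows.append({"protein_id": pid, "batch": batch,
                             "contrast": "TiO2_vs_UT", "log2fc": 2.0,
                             "p": 0.001, "q": 0.01, "hit": True})
        return pd.DataFrame(rows)

    def test_intersection_counts(self):
        out = overlap_summary(self._results({"b1": ["A", "B"], "b2": ["B", "C"]}))
        assert out.loc[0, "n_shared"] == 1
        assert out.loc[0, "shared_proteins"] == "B"

    def test_disjoint_and_identical_sets(self):
        assert overlap_summary(
            self._results({"b1": ["A"], "b2": ["B"]}))["n_shared"].iloc[0] == 0
        assert overlap_summary(
            self._results({"b1": ["A", "B", "C"],
                           "b2": ["A", "B", "C"]}))["n_shared"].iloc[0] == 3
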