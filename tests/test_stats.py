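"""Group statistics: signed-rank, FDR, map-effect ANOVA, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numadapt.stats import (
    fdr_adjust,
    map_effect_anova,
    per_map_signed_rank,
    region_correlations,
    signed_rank_test,
    tuned_effect_summaries,
)
from numadapt.synth import generate_reduction_examples


def exact_signed_rank_p(values):
    """Brute-force two-sided signed-rank p by enumerating all 2^n sign
    assignments of the ranked absolute values (no ties, no zeros)."""
    d = np.asarray(values, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    m = 2**n
    p_low = np.sum(ws <= w_obs) / m
    p_high = np.sum(ws >= w_obs) / m
    return min(1.0, 2 * min(p_low, p_high))


class TestSignedRank:
    def test_eight_positive_differences_exact_p(self):
        res = signed_rank_test(np.arange(1.0, 9.0))
        assert res.p_value == pytest.approx(2 / 256, abs=1e-15)
        assert res.n == 8

    def test_symmetric_values_give_p_one(self):
        res = signed_rank_test([1, -1, 2, -2, 3, -3])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [6, 8, 10, 12])
    def test_exact_p_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            x = rng.normal(0.3, 1.0, n)
            res = signed_rank_test(x)
            assert res.p_value == pytest.approx(exact_signed_rank_p(x),
                                                abs=1e-12)

    def test_all_zero_differences_warns_p_one(self):
        with pytest.warns(RuntimeWarning):
            res = signed_rank_test(np.zeros(8))
        assert res.p_value == 1.0

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 1.0, 40)
        res = signed_rank_test(x)
        assert 0 < res.p_value < 1


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])

    def test_hand_computed_examples(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(fdr_adjust([0.2, 0.9]), [0.4, 0.9])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_matches_step_up_definition(self, ps):
        """BH: adjusted p_(i) = min over j >= i of min(1, m p_(j) / j)."""
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="stable")
        stepped = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    def test_monotone_after_reordering_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.random(15)
        adj = fdr_adjust(p)
        assert np.all((adj >= p - 1e-15) & (adj <= 1.0))
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestPerMapSignedRank:
    def test_fdr_family_spans_maps(self):
        rng = np.random.default_rng(3)
        rows = []
        for m in ["V1", "V2", "V3"]:
            for h in range(8):
                rows.append({"map_label": m,
                             "value": rng.normal(0.5, 0.3)})
        out = per_map_signed_rank(pd.DataFrame(rows), "value")
        assert len(out) == 3
        np.testing.assert_allclose(
            out["p_adjusted"], fdr_adjust(out["p_value"]))


def classical_two_way_anova_F(df):
    """Hand sums-of-squares two-way ANOVA (balanced, one obs per cell)."""
    y = df.pivot(index="participant", columns="map_label", values="y").to_numpy()
    a, b = y.shape  # participants x maps
    grand = y.mean()
    ss_map = a * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_part = b * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_map - ss_part
    df_map, df_err = b - 1, (a - 1) * (b - 1)
    return (ss_map / df_map) / (ss_err / df_err), df_map, df_err


class TestMapEffectAnova:
    def _table(self, rng, n_part=6, maps=("V1", "V2", "V3", "V3AB"),
               effect=0.0):
        rows = []
        for p in range(n_part):
            for j, m in enumerate(maps):
                rows.append({"participant": f"P{p}", "map_label": m,
                             "proportional_reduction":
                                 effect * j + rng.normal(0, 0.1)})
        return pd.DataFrame(rows)

    def test_matches_hand_sums_of_squares_on_balanced_table(self, rng):
        tab = self._table(rng)
        res = map_effect_anova(tab)
        tab2 = tab.rename(columns={"proportional_reduction": "y"})
        F, df_map, df_err = classical_two_way_anova_F(tab2)
        assert res["F"] == pytest.approx(F, rel=1e-9)
        assert res["df"] == (df_map, df_err)

    def test_identical_values_give_zero_F(self):
        rows = [{"participant": p, "map_label": m,
                 "proportional_reduction": 0.5}
                for p in ("P1", "P2") for m in ("V1", "V2")]
        res = map_effect_anova(pd.DataFrame(rows))
        assert res["F"] == pytest.approx(0.0, abs=1e-20)

    def test_single_map_rejected(self):
        rows = [{"participant": p, "map_label": "V1",
                 "proportional_reduction": 0.5} for p in ("P1", "P2")]
        with pytest.raises(ValueError):
            map_effect_anova(pd.DataFrame(rows))

    def test_strong_gradient_detected_and_tukey_orders_extremes(self):
        hits, orders = 0, 0
        for rep in range(20):
            tab = generate_reduction_examples(
                hierarchy_gradient=0.1, noise_sd=0.03, seed=1000 + rep)
            res = map_effect_anova(tab)
            hits += res["p"] < 0.001
            tk = res["tukey"]
            row = tk[((tk["group1"] == "V1") & (tk["group2"] == "V3AB"))
                     | ((tk["group1"] == "V3AB") & (tk["group2"] == "V1"))]
            meandiff = float(row["meandiff"].iloc[0])
            lo = float(row["group1"].iloc[0] == "V1")
            orders += (meandiff > 0) == bool(lo)
        assert hits == 20
        assert orders >= 19

    def test_type_one_error_near_nominal_without_gradient(self):
        rejections = 0
        for rep in range(100):
            tab = generate_reduction_examples(
                hierarchy_gradient=0.0, noise_sd=0.1, seed=2000 + rep)
            rejections += map_effect_anova(tab)["p"] < 0.05
        assert 0.0 <= rejections / 100 <= 0.12


class TestRegionCorrelations:
    def test_perfect_linear_relation(self):
        a = np.arange(8.0)
        res = region_correlations(a, 2 * a)
        assert res["r"] == pytest.approx(1.0)

    def test_four_point_oracle_against_covariance_formula(self):
        a = np.array([1.0, 2.0, 4.0, 7.0])
        b = np.array([3.0, 1.0, 5.0, 6.0])
        r_oracle = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        res = region_correlations(a, b)
        assert res["r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_independent_normals_have_near_zero_mean_r(self):
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(1000):
            a, b = rng.normal(size=(2, 16))
            am, bm = a - a.mean(), b - b.mean()
            rs.append((am @ bm) / np.sqrt((am @ am) * (bm @ bm)))
        assert abs(np.mean(rs)) < 0.03

    def test_pairwise_complete_and_degenerate_inputs(self):
        res = region_correlations([1, 2, np.nan, 4, 5], [2, 4, 6, np.nan, 10])
        assert res["n"] == 3
        assert np.isnan(res["r"])  # < 4 complete pairs -> undefined
        res = region_correlations([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert np.isnan(res["r"])  # zero variance

    def test_normality_flag_from_anderson_darling(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=200)
        res = region_correlations(a, a + rng.normal(size=200))
        assert res["normality_ok"] is True
        res = region_correlations(a, a + rng.standard_cauchy(200))
        assert res["normality_ok"] is False


class TestTunedEffectSummaries:
    def test_delta_r2_and_preference_change_slope(self):
        rows = []
        for v, (pref_c, d) in enumerate([(1.0, 0.1), (1.5, 0.2), (2.0, 0.3)]):
            for cond, pref, r2 in [("changing", pref_c, 0.6),
                                   ("low", pref_c + d, 0.5),
                                   ("high", pref_c - d, 0.3)]:
                rows.append({
                    "voxel_id": f"v{v}", "participant": "P01",
                    "hemisphere": "L", "map_label": "LO1",
                    "condition": cond, "model_class": "tuned",
                    "pref_log": pref, "tuned_r2": r2,
                })
        out = tuned_effect_summaries(pd.DataFrame(rows))
        assert len(out) == 1
        assert out.loc[0, "delta_r2"] == pytest.approx(0.2)
        # pref change (low - high) = 2d rises by 0.2 per 0.5 of pref -> 0.4
        assert out.loc[0, "pref_change_slope"] == pytest.approx(0.4)

    def test_monotonic_voxels_ignored(self):
        rows = [{"voxel_id": "v", "participant": "P01", "hemisphere": "L",
                 "map_label": "V1", "condition": c, "model_class": "monotonic",
                 "pref_log": 1.0, "tuned_r2": 0.5}
                for c in ("low", "high", "changing")]
        assert tuned_effect_summaries(pd.DataFrame(rows)).empty
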