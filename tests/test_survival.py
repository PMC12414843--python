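"""Expression transform, signature scoring, quartiles, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmtdea import (
    km_estimator,
    log2p1,
    logrank_test,
    quartile_groups,
    signature_score,
)
from tmtdea.simulate import SurvivalParams, generate_survival
from tmtdea.survival import DEFAULT_SIGNATURE, group_anova, survival_comparison


class TestTransform:
    @pytest.mark.parametrize("x,expected", [(0, 0), (1, 1), (3, 2), (7, 3)])
    def test_log2p1_values(self, x, expected):
        assert log2p1(x) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2p1(-0.5)


class TestGroupAnova:
    def test_null_groups_give_small_f(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, (1, 90)), index=["G1"],
            columns=[f"S{i}" for i in range(90)],
        )
        groups = pd.Series(np.repeat(["a", "b", "c"], 30), index=expr.columns)
        f, p = group_anova(expr, "G1", groups)
        assert p > 0.01

    def test_p_matches_quadrature_of_f_tail(self, rng):
        expr = pd.DataFrame(
            [np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10),
                             rng.normal(2, 1, 10)])],
            index=["G1"], columns=[f"S{i}" for i in range(30)],
        )
        groups = pd.Series(np.repeat(["a", "b", "c"], 10), index=expr.columns)
        f, p = group_anova(expr, "G1", groups)
        from scipy.integrate import quad

        tail, _ = quad(lambda x: stats.f.pdf(x, 2, 27), f, np.inf)
        assert p == pytest.approx(tail, rel=1e-6)

    def test_unknown_gene_raises(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["a", "b"])
        with pytest.raises(KeyError):
            group_anova(expr, "G2", pd.Series(["x", "y"], index=["a", "b"]))


class TestSignatureScore:
    def _expr(self, values):
        return pd.DataFrame(values, index=list(DEFAULT_SIGNATURE))

    def test_constant_genes_give_that_value(self):
        expr = self._expr(np.full((6, 4), 2.5))
        assert (signature_score(expr) == 2.5).all()

    def test_two_gene_hand_arithmetic(self):
        expr = pd.DataFrame([[1.0], [3.0]], index=["A", "B"], columns=["s"])
        assert signature_score(expr, ["A", "B"])["s"] == pytest.approx(2.0)

    def test_matches_per_sample_recompute(self, rng):
        expr = self._expr(rng.normal(5, 2, (6, 20)))
        scores = signature_score(expr)
        for s in expr.columns:
            assert scores[s] == pytest.approx(expr[s].mean())

    def test_gene_order_invariance(self, rng):
        expr = self._expr(rng.normal(5, 2, (6, 10)))
        a = signature_score(expr, list(DEFAULT_SIGNATURE))
        b = signature_score(expr, list(DEFAULT_SIGNATURE)[::-1])
        pd.testing.assert_series_equal(a, b)

    def test_missing_genes_listed(self):
        expr = pd.DataFrame([[1.0]], index=["COL2A1"], columns=["s"])
        with pytest.raises(KeyError, match="THBS1"):
            signature_score(expr, ["COL2A1", "THBS1"])


class TestQuartiles:
    def test_scores_1_to_8(self):
        labels = quartile_groups(pd.Series(range(1, 9), dtype=float))
        # linear interpolation: Q1 = 2.75, Q3 = 6.25
        assert list(labels) == ["lower", "lower", "middle", "middle",
                                "middle", "middle", "upper", "upper"]

    def test_symmetric_scores_balanced(self, rng):
        x = rng.normal(0, 1, 101)
        scores = pd.Series(np.concatenate([x, -x, [0.0]]))
        labels = quartile_groups(scores)
        assert (labels == "lower").sum() == (labels == "upper").sum()

    def test_cohort_821_quartile_sizes(self, rng):
        scores = pd.Series(rng.normal(0, 1, 821))
        labels = quartile_groups(scores)
        assert abs((labels == "lower").sum() - 205) <= 1
        assert abs((labels == "upper").sum() - 205) <= 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            quartile_groups(pd.Series([1.0] * 20))
        with pytest.raises(ValueError):
            quartile_groups(pd.Series([1.0, 2.0, 3.0]))

    def test_boundary_ties_go_to_extremes(self):
        scores = pd.Series([0, 0, 0, 1, 2, 3, 9, 9, 9, 9], dtype=float)
        labels = quartile_groups(scores)
        assert (labels[scores == 0] == "lower").all()
        assert (labels[scores == 9] == "upper").all()


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = km_estimator([5, 8, 12], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_no_censoring_counting_closed_form(self, rng):
        times = rng.permutation(np.arange(1.0, 11.0))
        km = km_estimator(times, np.ones(10, int))
        for t in range(1, 11):
            alive = (times > t).sum()
            s = km.loc[km["time"] <= t, "survival"].iloc[-1]
            assert s == pytest.approx(alive / 10)

    def test_monotone_and_bounded(self, rng):
        times = rng.exponential(10, 50)
        events = rng.integers(0, 2, 50)
        if events.sum() == 0:
            events[0] = 1
        km = km_estimator(times, events)
        s = km["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert s.min() >= 0.0 and s.max() <= 1.0
        assert km.loc[0, "survival"] == 1.0

    def test_mass_drop_with_simultaneous_events(self):
        km = km_estimator([5.0] * 10, [1] * 4 + [0] * 6)
        # 4 of 10 die at t=5 -> S(5) = 6/10
        assert km.loc[km["time"] == 5.0, "survival"].iloc[0] == pytest.approx(0.6)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_estimator([], [])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        ta, tb = rng.exponential(5, 12), rng.exponential(9, 15)
        ea, eb = rng.integers(0, 2, 12), rng.integers(0, 2, 15)
        ea[0] = eb[0] = 1
        s1, p1 = logrank_test(ta, ea, tb, eb)
        s2, p2 = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_agrees_with_hand_computed_o_minus_e(self):
        # group A dies at 1 and 2; group B dies at 3 (no censoring)
        # t=1: n=4, nA=2, d=1, E_A=0.5, V=(1*2*2*3)/(16*3)=0.25
        # t=2: n=3, nA=1, d=1, E_A=1/3, V=(1*1*2*2)/(9*2)=2/9
        # t=3: n=2, nA=0, d=1, E_A=0,  V=0
        # O-E = (1-0.5)+(1-1/3) = 7/6; V = 0.25+2/9 = 17/36
        # chi2 = (7/6)^2/(17/36) = 49/17
        stat, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 0])
        assert stat == pytest.approx(49 / 17, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(49 / 17, 1), rel=1e-9)

    @staticmethod
    def _manual_logrank(times, events, is_a):
        """Independent O-E / hypergeometric-variance computation."""
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            n = at_risk.sum()
            n_a = (at_risk & is_a).sum()
            d = ((times == t) & (events == 1)).sum()
            d_a = ((times == t) & (events == 1) & is_a).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        return o_minus_e**2 / var

    def test_matches_manual_formula(self):
        times = np.array([2.0, 3.0, 5.0, 7.0, 8.0, 11.0, 12.0, 15.0, 17.0, 22.0])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        is_a = np.zeros(10, bool)
        is_a[:5] = True
        stat, _ = logrank_test(times[is_a], events[is_a],
                               times[~is_a], events[~is_a])
        assert stat == pytest.approx(self._manual_logrank(times, events, is_a),
                                     rel=1e-9)

    def test_agrees_with_permutation_oracle(self, rng):
        times = np.array([2.0, 3.0, 5.0, 7.0, 8.0, 11.0, 12.0, 15.0, 17.0, 22.0])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        is_a = np.zeros(10, bool)
        is_a[:5] = True
        stat_obs, p_obs = logrank_test(times[is_a], events[is_a],
                                       times[~is_a], events[~is_a])
        n_perm = 100_000
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(is_a)
            if self._manual_logrank(times, events, perm) >= stat_obs - 1e-12:
                exceed += 1
        p_perm = exceed / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        # chi-square approximation vs exact permutation at n=10
        assert abs(p_obs - p_perm) < max(5 * se, 0.05)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestEndToEndSurvival:
    def test_direction_recovery_rate(self, rng):
        """Positive hazard coefficient: upper quartile curve ends below lower."""
        hits = 0
        for rep in range(20):
            scores = pd.Series(np.random.default_rng(rep).normal(0, 1, 400))
            table = generate_survival(
                scores, SurvivalParams(coef=0.8), seed=1000 + rep
            )
            res = survival_comparison(table)
            s_upper = res["km_upper"]["survival"].iloc[-1]
            s_lower = res["km_lower"]["survival"].iloc[-1]
            hits += s_upper <= s_lower
        assert hits / 20 >= 0.95

    def test_type_i_error_calibrated(self):
        """Zero hazard coefficient: log-rank rejects at ~5%."""
        n_rep = 200
        rejections = 0
        for rep in range(n_rep):
            rng_r = np.random.default_rng(rep)
            scores = pd.Series(rng_r.normal(0, 1, 120))
            table = generate_survival(
                scores, SurvivalParams(coef=0.0), seed=5000 + rep
            )
            res = survival_comparison(table)
            rejections += res["logrank_p"] < 0.05
        rate = rejections / n_rep
        mc_se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * mc_se
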