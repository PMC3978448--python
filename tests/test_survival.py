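"""Survival statistics against independent oracles: brute-force partial
likelihood, exhaustive pair counting, hand-worked KM/log-rank tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cytorisk import (
    apply_threshold,
    cox_fit,
    harrells_c,
    km_estimate,
    logrank_test,
    median_dichotomize,
    optimal_cutpoint,
)

from conftest import random_survival


def outcome_frame(times, events, ids=None):
    ids = ids or [f"p{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=ids)


def brute_force_cox_beta(x, times, events):
    """Maximize the written-out Breslow partial likelihood (valid without
    tied event times) by direct numeric search."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)

    def negll(beta):
        ll = 0.0
        for i in np.flatnonzero(events):
            at_risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
        return -ll

    res = minimize_scalar(negll, bounds=(-20, 20), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def pair_counting_c(score, times, events):
    """Exhaustive-enumeration concordance oracle (same tie conventions)."""
    conc = tied = comp = 0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if i == j or not events[i] or times[j] <= times[i]:
                continue
            comp += 1
            if score[i] > score[j]:
                conc += 1
            elif score[i] == score[j]:
                tied += 1
    return (conc + 0.5 * tied) / comp


class TestCoxFit:
    def test_binary_covariate_matches_brute_force(self, rng):
        for _ in range(5):
            n = 25
            x = rng.integers(0, 2, n).astype(float)
            times = rng.exponential(1.0 / np.exp(0.8 * x))  # continuous: no ties
            events = rng.random(n) < 0.8
            if events.sum() < 3 or x.std() == 0:
                continue
            y = outcome_frame(times, events.astype(int))
            fit = cox_fit(pd.Series(x, index=y.index, name="x"), y)
            oracle = brute_force_cox_beta(x, times, events)
            assert fit.coefficients.iloc[0] == pytest.approx(oracle, abs=1e-6)

    def test_null_covariate_hr_near_one(self):
        score, y = random_survival(np.random.default_rng(42), 5000, hazard=0.3)
        fit = cox_fit(score.rename("x"), y)
        assert 0.93 < fit.hazard_ratios.iloc[0] < 1.07

    def test_zero_events_raise(self):
        y = outcome_frame([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            cox_fit(pd.Series([1.0, 2.0, 3.0], index=y.index), y)

    def test_missing_covariates_dropped_and_counted(self, rng):
        score, y = random_survival(rng, 60, score_effect=0.5)
        score.iloc[:5] = np.nan
        fit = cox_fit(score.rename("x"), y)
        assert fit.n_dropped == 5 and fit.n == 55

    def test_hr_equals_exp_coef_and_ci_brackets(self, rng):
        score, y = random_survival(rng, 120, score_effect=0.6)
        fit = cox_fit(score.rename("x"), y)
        assert fit.hazard_ratios.iloc[0] == pytest.approx(
            np.exp(fit.coefficients.iloc[0]))
        assert fit.ci_lower.iloc[0] < fit.hazard_ratios.iloc[0] < fit.ci_upper.iloc[0]

    def test_binary_coefficient_sign_tracks_incidence(self, rng):
        # no censoring, exponential times: the arm with shorter times gets
        # the positive coefficient
        n = 200
        arm = np.repeat([0.0, 1.0], n // 2)
        times = np.where(arm == 1, rng.exponential(0.5, n), rng.exponential(2.0, n))
        y = outcome_frame(times, [1] * n)
        fit = cox_fit(pd.Series(arm, index=y.index, name="arm"), y)
        assert fit.coefficients.iloc[0] > 0


class TestHarrellsC:
    def test_perfect_ordering_no_censoring(self):
        y = outcome_frame([1, 2, 3, 4], [1, 1, 1, 1])
        c, _ = harrells_c(pd.Series([4.0, 3.0, 2.0, 1.0], index=y.index), y)
        assert c == 1.0

    def test_constant_score_half(self):
        y = outcome_frame([1, 2, 3, 4], [1, 1, 0, 1])
        c, _ = harrells_c(pd.Series([2.0] * 4, index=y.index), y)
        assert c == 0.5

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(25):
            score, y = random_survival(rng, int(rng.integers(5, 30)))
            try:
                c, _ = harrells_c(score, y)
            except ValueError:
                continue
            oracle = pair_counting_c(score.to_numpy(), y["time"].to_numpy(),
                                     y["event"].to_numpy())
            assert c == pytest.approx(oracle)

    def test_complement_identity_without_score_ties(self, rng):
        score, y = random_survival(rng, 40)
        c_pos, _ = harrells_c(score, y)
        c_neg, _ = harrells_c(-score, y)
        assert c_pos + c_neg == pytest.approx(1.0)

    def test_agrees_with_lifelines_on_untied_data(self, rng):
        from lifelines.utils import concordance_index

        score, y = random_survival(rng, 80, score_effect=0.7)
        c, _ = harrells_c(score, y)
        # lifelines orders by predicted survival time: higher risk = lower
        assert c == pytest.approx(
            concordance_index(y["time"], -score, y["event"]))


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_estimate(outcome_frame([1, 2, 3], [0, 0, 0]))
        assert km.survival_at(2.5) == 1.0

    def test_hand_product_limit_table(self):
        # events at 1, 2, 3; one censored at 2.5:
        # S(1)=3/4, S(2)=3/4*2/3=1/2, S(3)=1/2*(1-1/1)=0
        km = km_estimate(outcome_frame([1, 2, 2.5, 3], [1, 1, 0, 1]))
        assert km.survival_at(1) == pytest.approx(0.75)
        assert km.survival_at(2) == pytest.approx(0.5)
        assert km.survival_at(2.9) == pytest.approx(0.5)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_uncensored_equals_empirical_survival(self, rng):
        times = rng.exponential(1.0, 50)
        km = km_estimate(outcome_frame(times, [1] * 50))
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert km.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_extrapolation_flag(self):
        km = km_estimate(outcome_frame([1, 2], [1, 0]))
        assert km.extrapolated_at(5.0) and not km.extrapolated_at(1.5)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 0, 1, 1, 0, 1]
        y = outcome_frame(times, events)
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=y.index)
        stat, p = logrank_test(y, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_six_subjects(self):
        # group a: events at 1, 3, censored 5; group b: events at 2, 4, 6.
        # Per event time (O−E for group a): t=1: 1−3/6; t=2: 0−2/5;
        # t=3: 1−2/4; t=4: 0−1/3; t=6: 0−0.  Sum O−E = 4/15;
        # V = 1/4 + 6/25 + 1/4 + 2/9 = 0.96222…; chi2 = (4/15)^2 / V.
        y = outcome_frame([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 1, 1])
        groups = pd.Series(list("aaabbb"), index=y.index)
        stat, p = logrank_test(y, groups)
        expected = (4 / 15) ** 2 / (1 / 4 + 6 / 25 + 1 / 4 + 2 / 9)
        assert stat == pytest.approx(expected, rel=1e-10)
        assert 0 < p < 1

    def test_empty_group_rejected(self):
        y = outcome_frame([1, 2], [1, 1])
        groups = pd.Series(["a", "a"], index=y.index)
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(y, groups)

    def test_chi_square_p_matches_permutation_null(self, rng):
        score, y = random_survival(rng, 40)
        groups = pd.Series(np.where(score > 0, "hi", "lo"), index=y.index)
        stat, p = logrank_test(y, groups)
        perm_more_extreme = 0
        n_perm = 800
        labels = groups.to_numpy().copy()
        for _ in range(n_perm):
            rng.shuffle(labels)
            s, _ = logrank_test(y, pd.Series(labels, index=y.index))
            perm_more_extreme += s >= stat
        perm_p = perm_more_extreme / n_perm
        assert abs(perm_p - p) < 4 * np.sqrt(max(p * (1 - p), 0.01) / n_perm) + 0.02


class TestDichotomization:
    def test_median_split_even(self):
        y = outcome_frame([1, 2, 3, 4], [1, 1, 1, 1])
        res = median_dichotomize(pd.Series([1.0, 2.0, 3.0, 4.0], index=y.index), y)
        assert res.n_low == 2 and res.n_high == 2

    def test_median_value_sample_goes_low(self):
        y = outcome_frame([1, 2, 3], [1, 1, 1])
        res = median_dichotomize(pd.Series([1.0, 2.0, 3.0], index=y.index), y)
        assert res.groups.loc["p1"] == "low"
        assert res.n_low == 2

    def test_constant_scores_rejected(self):
        y = outcome_frame([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="identical"):
            median_dichotomize(pd.Series([1.0, 1.0, 1.0], index=y.index), y)

    def test_optimal_cut_satisfies_constraint_and_beats_all(self, rng):
        score, y = random_survival(rng, 40, score_effect=0.8)
        res = optimal_cutpoint(score, y, min_frac=0.2)
        n = len(score)
        assert res.n_low >= 0.2 * n and res.n_high >= 0.2 * n
        # exhaustive check: no feasible midpoint has smaller P
        distinct = np.unique(score)
        for thr in (distinct[:-1] + distinct[1:]) / 2:
            n_low = int((score <= thr).sum())
            if n_low < 0.2 * n or n - n_low < 0.2 * n:
                continue
            groups = pd.Series(np.where(score <= thr, "l", "h"), index=score.index)
            _, p = logrank_test(y, groups)
            assert res.logrank_p <= p + 1e-12

    def test_optimal_cut_infeasible_raises(self):
        y = outcome_frame([1, 2, 3, 4], [1, 1, 1, 1])
        s = pd.Series([1.0, 1.0, 1.0, 5.0], index=y.index)
        with pytest.raises(ValueError, match="no threshold"):
            optimal_cutpoint(s, y, min_frac=0.4)

    def test_fixed_threshold_below_range_warns(self, rng):
        score, y = random_survival(rng, 20)
        with pytest.warns(UserWarning, match="empty"):
            res = apply_threshold(score, score.min() - 10, y)
        assert res.n_low == 0 and np.isnan(res.logrank_p)

    def test_fixed_threshold_at_median_matches_median_split(self, rng):
        score, y = random_survival(rng, 31)
        med = median_dichotomize(score, y)
        fixed = apply_threshold(score, float(np.median(score)), y)
        pd.testing.assert_series_equal(med.groups, fixed.groups)
        assert med.logrank_p == pytest.approx(fixed.logrank_p)

    def test_transferred_threshold_detects_strong_effect(self):
        # planted two-group hazard (HR 2.5) at a known latent split:
        # the transferred threshold yields significant separation in >= 95%
        # of replicates at n = 200
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            n = 200
            score = rng.standard_normal(n)
            high = score > 0
            times = rng.exponential(1.0 / (0.2 * np.where(high, 2.5, 1.0)))
            cens = rng.uniform(0, 10, n)
            y = outcome_frame(np.minimum(times, cens), (times <= cens).astype(int))
            res = apply_threshold(pd.Series(score, index=y.index), 0.0, y)
            hits += res.logrank_p < 0.05
        assert hits / n_rep >= 0.95
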