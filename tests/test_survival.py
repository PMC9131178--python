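"""Survival machinery against hand computations, brute-force oracles and
an independent library fit."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from histoadi.survival import (
    cox_fit,
    find_cutpoint,
    km_estimate,
    logrank_test,
    median_split,
    stratify_and_test,
)
from histoadi.synthetic import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles

def km_oracle(time, event):
    """Product-limit from the definition: walk distinct event times."""
    time, event = np.asarray(time, float), np.asarray(event, int)
    out = {}
    s = 1.0
    for t in sorted(set(time[event == 1])):
        n = sum(1 for v in time if v >= t)
        d = sum(1 for v, e in zip(time, event) if v == t and e == 1)
        s *= 1.0 - d / n
        out[t] = s
    return out


def logrank_oracle(time_a, event_a, time_b, event_b):
    """Observed-minus-expected events in group a, via scipy hypergeometric."""
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    in_a = np.concatenate([np.ones(len(time_a), bool), np.zeros(len(time_b), bool)])
    u = 0.0
    for t in sorted(set(time[event == 1])):
        risk = time >= t
        n, n_a = int(risk.sum()), int((risk & in_a).sum())
        dying = (time == t) & (event == 1)
        d, d_a = int(dying.sum()), int((dying & in_a).sum())
        u += d_a - sps.hypergeom(n, n_a, d).mean()  # d deaths drawn from n at risk
    return u, None


def logrank_var_oracle(time_a, event_a, time_b, event_b):
    """Sum of finite-population hypergeometric variances."""
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    in_a = np.concatenate([np.ones(len(time_a), bool), np.zeros(len(time_b), bool)])
    var = 0.0
    for t in sorted(set(time[event == 1])):
        risk = time >= t
        n, n_a = int(risk.sum()), int((risk & in_a).sum())
        d = int(((time == t) & (event == 1)).sum())
        if n > 1:  # a singleton risk set is deterministic: zero variance
            var += sps.hypergeom(n, n_a, d).var()
    return var


class TestKaplanMeier:
    def test_all_censored_survival_is_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_three_events_hand_product(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_shrinks_risk_set(self):
        # times 1, 2+, 3: S(1) = 2/3, then the last subject dies -> S(3) = 0
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == 0.0

    def test_censored_at_event_time_still_at_risk(self):
        # subject censored exactly at t=2 counts in the risk set at t=2
        curve = km_estimate([1.0, 2.0, 2.0, 3.0], [1, 1, 0, 1])
        assert curve.at_risk[curve.event_times == 2.0][0] == 3

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])

    @given(
        times=st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=12),
        data=st.data(),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_oracle_on_small_instances(self, times, data):
        events = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=1),
                min_size=len(times),
                max_size=len(times),
            )
        )
        curve = km_estimate([float(t) for t in times], events)
        oracle = km_oracle(times, events)
        assert curve.event_times.size == len(oracle)
        for t, s in oracle.items():
            assert curve.survival_at(t) == pytest.approx(s, abs=1e-12)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        res = logrank_test(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_toy_matches_hypergeometric_oracle(self):
        ta, ea = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 0])
        tb, eb = np.array([2.0, 4.0, 6.0]), np.array([1, 1, 1])
        res = logrank_test(ta, ea, tb, eb)
        u, _ = logrank_oracle(ta, ea, tb, eb)
        var = logrank_var_oracle(ta, ea, tb, eb)
        # hypergeom.var already carries the (n-d)/(n-1) finite correction
        assert res.chi2 == pytest.approx(u**2 / var, abs=1e-12)

    def test_tied_toy_matches_oracle(self):
        ta, ea = np.array([1.0, 1.0, 2.0, 4.0]), np.array([1, 1, 0, 1])
        tb, eb = np.array([1.0, 2.0, 3.0, 3.0]), np.array([0, 1, 1, 1])
        res = logrank_test(ta, ea, tb, eb)
        u, _ = logrank_oracle(ta, ea, tb, eb)
        var = logrank_var_oracle(ta, ea, tb, eb)
        assert res.chi2 == pytest.approx(u**2 / var, abs=1e-12)

    def test_group_swap_invariance(self):
        ta, ea = np.array([1.0, 3.0, 5.0, 7.0]), np.array([1, 1, 1, 0])
        tb, eb = np.array([2.0, 4.0, 6.0]), np.array([1, 0, 1])
        assert logrank_test(ta, ea, tb, eb).chi2 == pytest.approx(
            logrank_test(tb, eb, ta, ea).chi2, abs=1e-12
        )

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="at least one event"):
            logrank_test([1.0], [0], [2.0], [0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1.0, 2.0, 3.0], [1, 1, 1], [1.0, 1.0, 1.0])

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))  # continuous: no ties
        e = rng.integers(0, 2, size=n)
        e[0] = 1
        efron = cox_fit(t, e, x, ties="efron")
        breslow = cox_fit(t, e, x, ties="breslow")
        assert efron.beta == pytest.approx(breslow.beta, abs=1e-10)
        assert efron.se == pytest.approx(breslow.se, abs=1e-10)

    def test_matches_lifelines_with_ties(self):
        # independent-library cross-check, Efron handling on tied data
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(8)
        n = 120
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(np.exp(-0.7 * x)) * 4)  # rounded -> ties
        t = np.maximum(t, 1.0)
        e = (rng.random(n) < 0.8).astype(int)
        ours = cox_fit(t, e, x)
        cph = lifelines.CoxPHFitter()
        cph.fit(
            pd.DataFrame({"T": t, "E": e, "x": x}), duration_col="T", event_col="E"
        )
        assert ours.beta == pytest.approx(float(cph.params_["x"]), abs=1e-6)
        assert ours.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-6)

    def test_parameter_recovery_true_hr_2(self):
        spec = CohortSpec(
            n_patients=1000,
            true_log_hr=np.log(2.0),
            true_cutpoint=0.25,
            censoring_rate=0.0,
            seed=11,
        )
        cohort = generate_cohort(spec)
        fit = cox_fit(
            cohort["time"], cohort["event"], (cohort["adi"] > 0.25).astype(float)
        )
        assert fit.converged
        assert abs(fit.beta - np.log(2.0)) <= 0.15
        assert fit.ci_low <= fit.hr <= fit.ci_high

    def test_bias_shrinks_with_n(self):
        errors = []
        for n, seed in ((250, 1), (1000, 2), (4000, 3)):
            cohort = generate_cohort(
                CohortSpec(
                    n_patients=n,
                    true_log_hr=np.log(2.0),
                    censoring_rate=0.0,
                    seed=seed,
                )
            )
            fit = cox_fit(
                cohort["time"], cohort["event"], (cohort["adi"] > 0.25).astype(float)
            )
            errors.append(abs(fit.beta - np.log(2.0)))
        assert errors[-1] < 0.1  # near-unbiased at n = 4000

    def test_separation_flagged(self):
        # covariate perfectly orders the event times: monotone likelihood
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, dtype=int)
        x = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        fit = cox_fit(t, e, x)
        assert not fit.converged


class TestCutpoint:
    def test_perfect_separation_lands_between_groups(self):
        t = np.concatenate([np.linspace(1, 2, 25), np.linspace(10, 20, 25)])
        e = np.ones(50, dtype=int)
        scores = np.array([0.9] * 25 + [0.1] * 25)  # high score, short survival
        res = find_cutpoint(t, e, scores, minprop=0.1)
        assert 0.1 < res.cutpoint < 0.9

    def test_equals_brute_force_on_n30(self):
        rng = np.random.default_rng(21)
        n = 30
        scores = rng.random(n)
        t = rng.exponential(1.0, size=n) + 0.01
        e = rng.integers(0, 2, size=n)
        e[:3] = 1
        minprop = 0.1
        res = find_cutpoint(t, e, scores, minprop=minprop)

        # brute force: every feasible midpoint, standardized statistic
        distinct = np.unique(scores)
        best_stat, best_cut = -1.0, None
        for c in (distinct[:-1] + distinct[1:]) / 2:
            high = scores > c
            k = min(high.sum(), n - high.sum())
            if k < minprop * n:
                continue
            u, _ = logrank_oracle(t[high], e[high], t[~high], e[~high])
            var = logrank_var_oracle(t[high], e[high], t[~high], e[~high])
            stat = abs(u) / np.sqrt(var) if var > 0 else 0.0
            if stat > best_stat + 1e-12:
                best_stat, best_cut = stat, c
        assert res.cutpoint == pytest.approx(best_cut, abs=1e-12)
        assert res.statistic == pytest.approx(best_stat, abs=1e-9)

    def test_minprop_respected(self):
        t = np.linspace(1, 10, 20)
        e = np.ones(20, dtype=int)
        scores = np.arange(20) / 20.0
        res = find_cutpoint(t, e, scores, minprop=0.25)
        n_high = (scores > res.cutpoint).sum()
        assert min(n_high, 20 - n_high) >= 5

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            find_cutpoint([1.0, 2.0], [1, 1], [0.5, 0.5])


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split([0.1, 0.2, 0.3, 0.4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_median_subject_goes_low(self):
        labels = median_split([0.1, 0.2, 0.3])  # median is 0.2
        assert list(labels) == ["low", "low", "high"]

    def test_permutation_invariance(self):
        scores = np.array([0.4, 0.1, 0.3, 0.2])
        perm = np.array([2, 0, 3, 1])
        assert list(median_split(scores)[perm]) == list(median_split(scores[perm]))

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            median_split([0.3, 0.3, 0.3])


class TestStratifyAndTest:
    def test_subgroup_all_equals_unfiltered(self):
        cohort = generate_cohort(
            CohortSpec(n_patients=120, true_log_hr=np.log(2.0), seed=17)
        )
        full = stratify_and_test(cohort["time"], cohort["event"], cohort["adi"])
        masked = stratify_and_test(
            cohort["time"],
            cohort["event"],
            cohort["adi"],
            subgroup_mask=np.ones(len(cohort), dtype=bool),
        )
        assert full.threshold == masked.threshold
        assert full.logrank.p_value == masked.logrank.p_value
        assert full.cox.hr == masked.cox.hr

    def test_median_method(self):
        cohort = generate_cohort(CohortSpec(n_patients=80, seed=4))
        res = stratify_and_test(
            cohort["time"], cohort["event"], cohort["adi"], method="median"
        )
        assert res.method == "median"
        assert res.n_high + res.n_low == 80

    def test_few_events_flagged_unreliable(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 0, 0, 0, 0, 0])
        scores = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.8])
        res = stratify_and_test(t, e, scores, method="median")
        assert not res.reliable
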