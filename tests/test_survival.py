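"""Kaplan-Meier and Cox regression against independent references."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import rxpersist as rx
from rxpersist.errors import CollinearityError
from rxpersist.survival import _loglik_grad_info

from oracles import brute_cox_mle_1d, ecdf_survivor


class TestKaplanMeier:
    def test_worked_example_exact(self):
        """Hand-computed product limit: 4/5, then x2/3, then x1/2."""
        curve = rx.km_estimate([1, 2, 3, 4, 5], [True, False, True, True, False])
        assert curve.survival.tolist() == [
            float(Fraction(4, 5)),
            float(Fraction(8, 15)),
            float(Fraction(4, 15)),
        ]
        assert curve.n_at_risk.tolist() == [5, 3, 2]

    def test_step_function_readout(self):
        curve = rx.km_estimate([1, 2, 3, 4, 5], [True, False, True, True, False])
        assert curve.survival_at(0) == 1.0
        assert curve.survival_at(0.5) == 1.0  # before the first event
        assert rx.km_survival_at(curve, 3.5) == float(Fraction(8, 15))
        assert curve.survival_at(100) == float(Fraction(4, 15))

    def test_all_censored_flat_at_one(self):
        curve = rx.km_estimate([3.0, 7.0, 9.0], [False, False, False])
        assert curve.event_times.size == 0
        assert curve.survival_at(1000) == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            t = np.round(rng.exponential(10, size=n), 1) + 0.1
            curve = rx.km_estimate(t, np.ones(n, dtype=bool))
            for q in rng.exponential(10, size=5):
                assert curve.survival_at(q) == pytest.approx(
                    ecdf_survivor(t, q), abs=1e-12
                )

    def test_survival_and_greenwood_match_statsmodels(self):
        from statsmodels.duration.survfunc import SurvfuncRight

        rng = np.random.default_rng(3)
        t = rng.exponential(10, 80) + 0.01
        e = rng.random(80) < 0.7
        curve = rx.km_estimate(t, e)
        sf = SurvfuncRight(t, e.astype(int))
        theirs = pd.Series(sf.surv_prob, index=sf.surv_times)
        theirs_se = pd.Series(sf.surv_prob_se, index=sf.surv_times)
        for time, s, se in zip(curve.event_times, curve.survival, curve.greenwood_se):
            assert s == pytest.approx(theirs.loc[time], abs=1e-12)
            if np.isnan(se):  # S has hit zero; variance undefined in both
                assert np.isnan(theirs_se.loc[time])
            else:
                assert se == pytest.approx(theirs_se.loc[time], abs=1e-12)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            rx.km_estimate([], [])
        with pytest.raises(ValueError):
            rx.km_estimate([0.0, 1.0], [True, True])

    def test_accepts_survival_samples(self):
        samples = [rx.SurvivalSample(time=float(t), event=bool(e))
                   for t, e in [(1, 1), (2, 0), (3, 1)]]
        curve = rx.km_estimate(samples)
        assert curve.survival_at(1) == pytest.approx(2 / 3)


class TestCox:
    def test_mirrored_groups_give_null_coefficient(self):
        # both groups share the same event-time distribution
        t = np.array([1, 3, 5, 1, 3, 5], dtype=float)
        e = np.array([1, 1, 0, 1, 1, 0], dtype=bool)
        x = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        fit = rx.cox_fit(x, t, e)
        assert abs(fit.coef[0]) < 1e-8
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_six_subject_example_matches_enumerated_mle(self):
        """beta-hat equals the argmax of the exactly enumerated partial
        likelihood for the tie-free 6-subject dataset."""
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        e = np.array([1, 1, 1, 0, 1, 0], dtype=bool)
        x = np.array([1, 0, 1, 1, 0, 0], dtype=float)
        fit = rx.cox_fit(x, t, e, tol=1e-12)
        assert fit.coef[0] == pytest.approx(brute_cox_mle_1d(t, e, x), abs=1e-6)

    def test_matches_lifelines_small_datasets(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(99)
        for k in range(12):
            n = int(rng.integers(10, 30))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            t = rng.exponential(1 / np.exp(X @ rng.normal(0, 0.4, p)))
            if k % 3 == 0:
                t = np.ceil(t * 8)  # induce ties
            e = rng.random(n) < 0.8
            e[0] = True
            df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
            df["T"], df["E"] = t + 1e-3, e
            fit = rx.cox_fit(X, t + 1e-3, e, tol=1e-12)
            cph = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-10})
            assert np.allclose(fit.coef, cph.params_.to_numpy(), atol=1e-6)
            assert np.allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-6)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 2))
        t = rng.exponential(1, 40)  # continuous: ties have probability 0
        e = rng.random(40) < 0.7
        fa = rx.cox_fit(X, t, e, ties_method="efron", tol=1e-12)
        fb = rx.cox_fit(X, t, e, ties_method="breslow", tol=1e-12)
        assert np.array_equal(fa.coef, fb.coef)
        assert np.array_equal(fa.se, fb.se)
        assert fa.loglik == fb.loglik

    def test_loglik_nondecreasing_and_gradient_small(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(200, 3))
        t = np.ceil(rng.exponential(1 / np.exp(X @ [0.5, -0.5, 0.2])) * 30)
        e = rng.random(200) < 0.8
        fit = rx.cox_fit(X, t, e)
        assert fit.converged
        diffs = np.diff(fit.loglik_path)
        assert np.all(diffs >= -1e-10)
        # gradient at the solution (standardized scale) is numerically zero
        Xw = (X - X.mean(0)) / X.std(0)
        order = np.argsort(t, kind="stable")
        _, g, _ = _loglik_grad_info(
            fit.coef * X.std(0), Xw[order], t[order], e[order], "efron"
        )
        assert np.max(np.abs(g)) < 1e-6

    def test_parameter_recovery_true_hr_two(self):
        rng = np.random.default_rng(2718)
        X, t, e = rx.simulate_survival_data(5000, [np.log(2.0)], rng)
        fit = rx.cox_fit(X, t, e)
        assert abs(fit.coef[0] - np.log(2.0)) < 3 * fit.se[0]

    def test_collinear_design_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(CollinearityError) as err:
            rx.cox_fit(X, [1, 2, 3, 4], [1, 1, 1, 0])
        assert "b" in str(err.value) or "a" in str(err.value)

    def test_requires_events(self):
        with pytest.raises(ValueError):
            rx.cox_fit(np.ones((3, 1)), [1, 2, 3], [False, False, False])

    def test_summary_invariants(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 2))
        t = rng.exponential(1, 100)
        e = rng.random(100) < 0.6
        fit = rx.cox_fit(X, t, e)
        s = fit.summary()
        assert (s["hr"] > 0).all()
        assert (s["hr_ci_lower"] < s["hr"]).all()
        assert (s["hr"] < s["hr_ci_upper"]).all()
        assert ((s["p"] >= 0) & (s["p"] <= 1)).all()


def test_ci_coverage_near_nominal():
    """95% Wald CIs cover a true log-HR at close to nominal rate."""
    rng = np.random.default_rng(314159)
    beta = np.log(1.5)
    covered = 0
    reps = 300
    for _ in range(reps):
        X, t, e = rx.simulate_survival_data(200, [beta], rng, baseline_rate=0.003)
        fit = rx.cox_fit(X, t, e)
        lo, hi = fit.ci95
        covered += int(lo[0] <= np.exp(beta) <= hi[0])
    assert 0.91 <= covered / reps <= 0.985
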