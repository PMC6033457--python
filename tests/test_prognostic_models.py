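"""Cox / logistic fits, PH diagnostics, ROC and LOOCV."""

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from adchist.exceptions import InsufficientEventsError
from adchist.prognostic_models import (
    check_ph_assumption,
    fit_univariate_cox,
    fit_univariate_logistic,
    loocv_threshold,
    roc_analysis,
)


def efron_loglik_oracle(beta, times, events, x):
    """Independent direct-formula Efron partial log-likelihood."""
    ll = 0.0
    for tau in sorted({t for t, e in zip(times, events) if e}):
        risk = [i for i, t in enumerate(times) if t >= tau]
        tied = [i for i, (t, e) in enumerate(zip(times, events)) if t == tau and e]
        d = len(tied)
        s_r = sum(np.exp(beta * x[i]) for i in risk)
        s_d = sum(np.exp(beta * x[i]) for i in tied)
        ll += sum(beta * x[i] for i in tied)
        for ell in range(d):
            ll -= np.log(s_r - ell / d * s_d)
    return ll


def make_cohort(times, events, x):
    return pd.DataFrame(
        {"followup_months": times, "doc_event": events, "x": np.asarray(x, float)}
    )


class TestCoxFit:
    def test_matches_golden_section_oracle_on_toy_set(self):
        df = make_cohort([1, 2, 3, 4], [1, 1, 1, 0], [2, 0, 1, 0])
        fit = fit_univariate_cox(df, "x")
        res = optimize.minimize_scalar(
            lambda b: -efron_loglik_oracle(
                b, df.followup_months.to_list(), df.doc_event.to_list(), df.x.to_numpy()
            ),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.converged
        assert fit.beta == pytest.approx(res.x, abs=1e-4)

    def test_monotone_likelihood_reported_as_non_convergence(self):
        # covariate perfectly ordering the event times: no finite maximizer
        df = make_cohort([1, 2, 3, 4], [1, 1, 1, 0], [2, 1, 0, 0])
        fit = fit_univariate_cox(df, "x")
        assert not fit.converged

    def test_efron_matches_lifelines_on_tied_data(self, rng):
        from lifelines import CoxPHFitter

        n = 80
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(scale=np.exp(-0.5 * x)) * 5)
        e = rng.random(n) < 0.7
        df = make_cohort(t, e.astype(int), x)
        fit = fit_univariate_cox(df, "x", ties="efron")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter().fit(df, "followup_months", "doc_event")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_breslow_differs_from_efron_on_ties(self, rng):
        x = rng.normal(size=40)
        t = np.ceil(rng.exponential(scale=np.exp(-0.6 * x)) * 3)
        df = make_cohort(t, np.ones(40, int), x)
        b_efron = fit_univariate_cox(df, "x", ties="efron").beta
        b_breslow = fit_univariate_cox(df, "x", ties="breslow").beta
        assert b_efron != pytest.approx(b_breslow, abs=1e-6)

    def test_score_test_agrees_with_logrank_for_binary_predictor(self):
        from adchist.prognostic_models import _cox_terms
        from lifelines.statistics import logrank_test

        # distinct times, no censoring, binary groups
        times = np.array([1.0, 2.5, 3.0, 4.5, 6.0, 7.5, 9.0, 11.0])
        events = np.ones(8, bool)
        x = np.array([1.0, 0, 1, 0, 1, 0, 0, 1])
        _, grad, info = _cox_terms(0.0, times, events, x, "breslow")
        score_stat = grad**2 / info
        ref = logrank_test(
            times[x == 1], times[x == 0], events[x == 1], events[x == 0]
        ).test_statistic
        assert score_stat == pytest.approx(ref, abs=1e-6)

    def test_simulated_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(scale=np.exp(-0.7 * x) / 0.05)
        c = rng.uniform(5, 60, n)
        df = make_cohort(np.minimum(t, c), (t <= c).astype(int), x)
        fit = fit_univariate_cox(df, "x")
        assert abs(fit.beta - 0.7) < 3 * fit.se

    def test_unit_scale_behaviour(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        t = rng.exponential(scale=np.exp(-0.4 * x) / 0.05)
        df = make_cohort(t, np.ones(60, int), x)
        f1 = fit_univariate_cox(df, "x", unit_scale=1.0)
        f2 = fit_univariate_cox(df, "x", unit_scale=0.1)
        assert f2.hazard_ratio == pytest.approx(np.exp(f1.beta * 0.1), rel=1e-9)
        # rescaling the covariate leaves the HR per stated unit unchanged
        df2 = df.assign(x=df.x * 10)
        f3 = fit_univariate_cox(df2, "x", unit_scale=1.0)
        assert f3.hazard_ratio == pytest.approx(f2.hazard_ratio, rel=1e-6)
        assert f1.ci95[0] < f1.hazard_ratio < f1.ci95[1]

    def test_constant_predictor_rejected(self):
        df = make_cohort([1, 2, 3, 4], [1, 1, 1, 0], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            fit_univariate_cox(df, "x")

    def test_insufficient_events_rejected(self):
        df = make_cohort([1, 2, 3, 4], [1, 0, 0, 0], [2, 1, 0, 3])
        with pytest.raises(InsufficientEventsError):
            fit_univariate_cox(df, "x")


class TestPHAssumption:
    @staticmethod
    def _sim_ph_true(seed, n=100, beta=0.5):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        t = rng.exponential(scale=np.exp(-beta * x) / 0.05)
        c = rng.uniform(5, 60, n)
        return make_cohort(np.minimum(t, c), (t <= c).astype(int), x)

    @staticmethod
    def _sim_sign_flip(seed, n=300, beta=1.5, lam=0.03, t0=20.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        e_std = rng.exponential(size=n)
        h1, h2 = lam * np.exp(beta * x), lam * np.exp(-beta * x)
        t = np.where(e_std < h1 * t0, e_std / h1, t0 + (e_std - h1 * t0) / h2)
        return make_cohort(np.minimum(t, 80.0), (t <= 80.0).astype(int), x)

    def test_type_one_error_near_alpha_under_true_ph(self):
        rej = sum(
            check_ph_assumption(None, self._sim_ph_true(1000 + s), "x").p < 0.05
            for s in range(200)
        )
        assert 0.01 <= rej / 200 <= 0.11

    def test_detects_sign_flipping_effect(self):
        rej = sum(
            check_ph_assumption(None, self._sim_sign_flip(2000 + s), "x").p < 0.05
            for s in range(40)
        )
        assert rej / 40 >= 0.8

    def test_tiny_cohort_is_undefined(self):
        df = make_cohort([1, 2], [1, 1], [0, 1])
        res = check_ph_assumption(None, df, "x")
        assert not res.defined
        assert np.isnan(res.p)


class TestLogisticFit:
    def test_closed_form_two_by_two_odds_ratio(self):
        # binary predictor, counts a/b/c/d = 3/1/1/3 -> OR = 9
        y = [1] * 3 + [1] + [0] + [0] * 3
        x = [1] * 3 + [0] + [1] + [0] * 3
        df = pd.DataFrame({"doc_within_3y": y, "x": x})
        fit = fit_univariate_logistic(df, "x")
        assert fit.converged
        assert fit.odds_ratio == pytest.approx(9.0, rel=1e-3)

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame({"doc_within_3y": [0, 0, 0, 1, 1, 1], "x": [1, 2, 3, 4, 5, 6.0]})
        fit = fit_univariate_logistic(df, "x")
        assert not fit.converged

    def test_simulated_parameter_recovery(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 2, 500)
        p = 1 / (1 + np.exp(-(-0.3 + 0.25 * x)))
        df = pd.DataFrame({"doc_within_3y": (rng.random(500) < p).astype(int), "x": x})
        fit = fit_univariate_logistic(df, "x")
        assert abs(fit.beta - 0.25) < 3 * fit.se
        assert fit.ci95[0] < fit.odds_ratio < fit.ci95[1]

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"doc_within_3y": [1, 1, 1], "x": [1, 2, 3.0]})
        with pytest.raises(ValueError):
            fit_univariate_logistic(df, "x")


def auc_oracle(scores, labels):
    """Exhaustive concordant-pair count in exact rational arithmetic."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                total += 1
            elif p == n:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, -1, 0], [1, 1, 1, 0, 0], "ge")
        assert res.auc == 1.0
        assert res.sensitivity == res.specificity == res.accuracy == 1.0

    def test_tied_pair_counts_one_half(self):
        res = roc_analysis([1, 2, 1, 0], [1, 1, 0, 0], "ge")
        assert res.auc == pytest.approx(float(auc_oracle([1, 2, 1, 0], [1, 1, 0, 0])))

    def test_label_inversion_maps_auc(self, rng):
        s = rng.normal(size=12)
        y = rng.integers(0, 2, 12)
        if y.all() or not y.any():
            y[0], y[1] = 0, 1
        a = roc_analysis(s, y, "ge").auc
        b = roc_analysis(s, 1 - y, "ge").auc
        assert a == pytest.approx(1 - b)

    def test_auc_equals_exhaustive_pair_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            s = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            y = rng.integers(0, 2, n)
            if y.all() or not y.any():
                continue
            res = roc_analysis(s, y, "ge")
            assert res.auc == pytest.approx(float(auc_oracle(s, y)), abs=1e-12)

    def test_youden_cutoff_maximises_j(self):
        s = np.array([0.1, 0.3, 0.35, 0.7, 0.9, 0.95])
        y = np.array([0, 0, 1, 0, 1, 1])
        res = roc_analysis(s, y, "ge")
        for c in np.unique(s):
            pred = s >= c
            j = (pred & (y == 1)).sum() / 3 + (~pred & (y == 0)).sum() / 3 - 1
            assert res.sensitivity + res.specificity - 1 >= j - 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1], "ge")


class TestLOOCV:
    @staticmethod
    def _frame(scores, labels):
        return pd.DataFrame({"padc_xlow": scores, "doc_within_3y": labels})

    def test_perfectly_separated_scores(self):
        cv = loocv_threshold(self._frame([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]), "padc_xlow")
        assert cv.accuracy == 1.0
        assert not cv.degenerate_folds

    def test_matches_fold_by_fold_oracle(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 2.5]
        labels = [0, 0, 0, 1, 1, 1]  # the 2.5 positive sits inside the negatives

        def youden_cutoff(s, y):
            v = sorted(set(s))
            cands = [v[0]] + [(a + b) / 2 for a, b in zip(v, v[1:])]
            best = None
            for c in cands:
                pred = [v >= c for v in s]
                sens = sum(p and t for p, t in zip(pred, y)) / sum(y)
                spec = sum((not p) and (not t) for p, t in zip(pred, y)) / (len(y) - sum(y))
                key = (sens + spec - 1, spec, c)
                if best is None or key > best[0]:
                    best = (key, c)
            return best[1]

        correct = 0
        for i in range(6):
            s = [v for j, v in enumerate(scores) if j != i]
            y = [v for j, v in enumerate(labels) if j != i]
            c = youden_cutoff(s, y)
            correct += (scores[i] >= c) == bool(labels[i])
        cv = loocv_threshold(self._frame(scores, labels), "padc_xlow")
        assert cv.accuracy == pytest.approx(correct / 6)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.normal(size=15)
        y = rng.integers(0, 2, 15)
        y[:2] = [0, 1]
        a = loocv_threshold(self._frame(s, y), "padc_xlow").accuracy
        b = loocv_threshold(self._frame(np.exp(s), y), "padc_xlow").accuracy
        assert a == b

    def test_degenerate_fold_flagged_and_majority_voted(self):
        cv = loocv_threshold(self._frame([1, 2, 3, 4, 10], [0, 0, 0, 0, 1]), "padc_xlow")
        assert cv.degenerate_folds == [4]
        assert cv.fold_predictions[4] == False  # noqa: E712 — majority class

    def test_fixed_cutoff_variant(self):
        df = self._frame([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        cv = loocv_threshold(df, "padc_xlow", fixed_cutoff=5.0)
        assert cv.accuracy == 1.0
        assert np.all(cv.fold_cutoffs == 5.0)
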