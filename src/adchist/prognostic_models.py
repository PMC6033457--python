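"""Univariate prognostic modelling for small survival cohorts.

Covers the four analysis tools applied per predictor:

* Cox proportional-hazards regression on follow-up time with death from
  cancer as the event. The single-covariate partial likelihood (Efron
  tie handling by default, Breslow optional) is maximised by Newton
  iteration; hazard ratios are reported per a stated covariate unit with
  Wald confidence intervals.
* A proportional-hazards diagnostic (scaled Schoenfeld residuals against
  Kaplan-Meier-transformed time); predictors failing it at alpha are
  flagged for exclusion.
* Logistic regression of the 3-year death outcome with Wald inference,
  with complete separation reported rather than silently diverging.
* ROC analysis: AUC as the tie-corrected Mann-Whitney statistic, cutoff
  chosen by maximal Youden J (ties broken toward higher specificity),
  and leave-one-out cross-validation of the resulting single-threshold
  classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .exceptions import InsufficientEventsError
from .histogram_features import ADCHistogramProfile

log = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "CoxFit",
    "LogisticFit",
    "ROCResult",
    "CVResult",
    "PHAssumptionResult",
    "fit_univariate_cox",
    "check_ph_assumption",
    "fit_univariate_logistic",
    "roc_analysis",
    "loocv_threshold",
]

_Z975 = sps.norm.ppf(0.975)


@dataclass
class PatientRecord:
    """One patient: histogram profile joined with outcome and staging.

    TNM grades are ordinal encodings (T: Tis/T2/T3/T4 -> 0-3,
    N: N0/N1/N2b/N3b -> 0-3, M: M0/M1 -> 0-1). ``doc_event`` marks death
    from cancer during follow-up; ``doc_within_3y`` the binary 3-year
    outcome (implied by ``doc_event`` in this cohort design).
    """

    id: str
    profile: Optional[ADCHistogramProfile]
    t_grade: int
    n_grade: int
    m_grade: int
    age: float
    age_ge_60: int
    margin_positive: int
    additional_treatment: int
    followup_months: float
    doc_event: int
    doc_within_3y: int

    def __post_init__(self):
        if self.followup_months <= 0:
            raise ValueError("follow-up must be positive")
        if self.doc_within_3y and not self.doc_event:
            raise ValueError("a 3-year cancer death implies an event")
        if not (0 <= self.t_grade <= 3 and 0 <= self.n_grade <= 3 and 0 <= self.m_grade <= 1):
            raise ValueError("TNM grades out of range")


@dataclass
class CoxFit:
    """Univariate Cox fit: hazard ratio per ``unit_scale`` covariate units."""

    hazard_ratio: float
    ci95: tuple[float, float]
    p: float
    unit_scale: float
    converged: bool
    beta: float
    se: float
    loglik: float
    n_events: int


@dataclass
class LogisticFit:
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    unit_scale: float
    converged: bool
    beta: float
    se: float


@dataclass
class PHAssumptionResult:
    """Proportional-hazards diagnostic outcome for one predictor."""

    p: float
    excluded: bool
    defined: bool


@dataclass
class ROCResult:
    auc: float
    cutoff: float
    direction: str
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class CVResult:
    fold_predictions: np.ndarray
    fold_cutoffs: np.ndarray
    accuracy: float
    degenerate_folds: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Cox partial likelihood


def _cox_terms(beta: float, times, events, x, ties: str):
    """Log partial likelihood, gradient and information for one covariate."""
    order = np.argsort(times, kind="stable")
    t, e, xv = times[order], events[order], x[order]
    eta = beta * xv
    w = np.exp(eta)
    wx = w * xv
    wxx = w * xv * xv

    loglik = grad = info = 0.0
    for tau in np.unique(t[e]):
        at_risk = t >= tau
        tied = (t == tau) & e
        d = int(tied.sum())
        s_r, s_rx, s_rxx = w[at_risk].sum(), wx[at_risk].sum(), wxx[at_risk].sum()
        s_d, s_dx, s_dxx = w[tied].sum(), wx[tied].sum(), wxx[tied].sum()
        loglik += eta[tied].sum()
        for ell in range(d):
            f = ell / d if ties == "efron" else 0.0
            phi = s_r - f * s_d
            phi1 = s_rx - f * s_dx
            phi2 = s_rxx - f * s_dxx
            loglik -= np.log(phi)
            grad_term = phi1 / phi
            grad -= grad_term
            info += phi2 / phi - grad_term**2
        grad += xv[tied].sum()
    return loglik, grad, info


def fit_univariate_cox(
    cohort: pd.DataFrame,
    predictor: str,
    unit_scale: float = 1.0,
    duration_col: str = "followup_months",
    event_col: str = "doc_event",
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 60,
) -> CoxFit:
    """Newton maximisation of the single-covariate Cox partial likelihood.

    The covariate is standardised internally for numerical stability; the
    reported hazard ratio is ``exp(beta * unit_scale)`` on the original
    covariate scale, with a 95% Wald interval. Monotone-likelihood
    separation is reported through ``converged = False``.

    Raises
    ------
    InsufficientEventsError
        If fewer than two events are present.
    ValueError
        If the predictor has zero variance or ``ties`` is unknown.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling '{ties}'")
    times = cohort[duration_col].to_numpy(dtype=float)
    events = cohort[event_col].to_numpy(dtype=bool)
    x = cohort[predictor].to_numpy(dtype=float)
    if events.sum() < 2:
        raise InsufficientEventsError("Cox fit needs at least 2 events")
    sd = x.std()
    if sd == 0:
        raise ValueError(f"predictor '{predictor}' is constant")
    xs = (x - x.mean()) / sd

    beta = 0.0
    loglik, grad, info = _cox_terms(beta, times, events, xs, ties)
    converged = False
    for _ in range(max_iter):
        if abs(grad) < tol:
            converged = True
            break
        if info <= 1e-12:
            break
        step = grad / info
        # step halving keeps the likelihood non-decreasing
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_terms(new_beta, times, events, xs, ties)
            if new_ll >= loglik - 1e-12:
                break
            step /= 2.0
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
    if abs(beta) > 15:  # e^15 per covariate sd: monotone likelihood
        converged = False
    if not converged:
        log.warning("Cox fit for '%s' did not converge (separation?)", predictor)

    se_int = 1.0 / np.sqrt(info) if info > 0 else np.inf
    beta_orig = beta / sd
    se_orig = se_int / sd
    z = beta_orig / se_orig if se_orig > 0 else np.inf
    with np.errstate(over="ignore"):  # separated fits may overflow to inf
        hr = float(np.exp(beta_orig * unit_scale))
        ci = (
            float(np.exp((beta_orig - _Z975 * se_orig) * unit_scale)),
            float(np.exp((beta_orig + _Z975 * se_orig) * unit_scale)),
        )
    return CoxFit(
        hazard_ratio=hr,
        ci95=ci,
        p=float(2 * sps.norm.sf(abs(z))),
        unit_scale=unit_scale,
        converged=converged,
        beta=float(beta_orig),
        se=float(se_orig),
        loglik=float(loglik),
        n_events=int(events.sum()),
    )


def check_ph_assumption(
    fit: Optional[CoxFit],
    cohort: pd.DataFrame,
    predictor: str,
    duration_col: str = "followup_months",
    event_col: str = "doc_event",
    alpha: float = 0.05,
) -> PHAssumptionResult:
    """Scaled-Schoenfeld-residual test of the proportional-hazards assumption.

    Tests for a nonzero slope of the scaled Schoenfeld residuals against
    Kaplan-Meier-transformed time; ``excluded`` is True when p < alpha,
    flagging the predictor for removal from the Cox analysis. Cohorts too
    small to support the diagnostic return ``defined = False``.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    if fit is not None and not fit.converged:
        return PHAssumptionResult(p=float("nan"), excluded=False, defined=False)
    df = cohort[[duration_col, event_col, predictor]].astype(float)
    if df[event_col].sum() < 3 or len(df) < 4:
        return PHAssumptionResult(p=float("nan"), excluded=False, defined=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col=duration_col, event_col=event_col)
            res = proportional_hazard_test(cph, df, time_transform="km")
        p = float(res.summary.loc[predictor, "p"].iloc[0]
                  if hasattr(res.summary.loc[predictor, "p"], "iloc")
                  else res.summary.loc[predictor, "p"])
    except Exception as err:  # diagnostic undefined on degenerate input
        log.warning("PH diagnostic undefined for '%s': %s", predictor, err)
        return PHAssumptionResult(p=float("nan"), excluded=False, defined=False)
    return PHAssumptionResult(p=p, excluded=bool(p < alpha), defined=True)


# ---------------------------------------------------------------------------
# Logistic regression


def fit_univariate_logistic(
    cohort: pd.DataFrame,
    predictor: str,
    unit_scale: float = 1.0,
    outcome_col: str = "doc_within_3y",
) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome on one predictor.

    Odds ratio reported per ``unit_scale`` covariate units with Wald CI.
    Complete or quasi-complete separation yields ``converged = False``.
    """
    import statsmodels.api as sm

    y = cohort[outcome_col].to_numpy(dtype=float)
    x = cohort[predictor].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    sd = x.std()
    if sd == 0:
        raise ValueError(f"predictor '{predictor}' is constant")
    xs = (x - x.mean()) / sd

    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(xs)).fit(disp=0, maxiter=200)
            beta_int = float(res.params[1])
            se_int = float(res.bse[1])
            mle_converged = bool(res.mle_retvals.get("converged", False))
        except Exception:  # perfect separation raises in some versions
            separated = True
            beta_int, se_int, mle_converged = np.inf, np.inf, False
    if not separated and (abs(beta_int) > 15 or not np.isfinite(se_int) or se_int > 1e3):
        separated = True
    converged = mle_converged and not separated
    if not converged:
        log.warning("logistic fit for '%s': separation / non-convergence", predictor)

    beta = beta_int / sd
    se = se_int / sd
    z = beta / se if (np.isfinite(se) and se > 0) else np.inf
    with np.errstate(over="ignore"):  # separated fits may overflow to inf
        odds = float(np.exp(beta * unit_scale)) if np.isfinite(beta) else float("inf")
        ci = (
            float(np.exp((beta - _Z975 * se) * unit_scale)),
            float(np.exp((beta + _Z975 * se) * unit_scale)),
        )
    return LogisticFit(
        odds_ratio=odds,
        ci95=ci,
        p=float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
        unit_scale=unit_scale,
        converged=converged,
        beta=float(beta),
        se=float(se),
    )


# ---------------------------------------------------------------------------
# ROC and cross-validation


def roc_analysis(scores: Sequence[float], labels: Sequence[int], direction: str = "ge") -> ROCResult:
    """AUC and Youden-optimal cutoff for a single continuous predictor.

    ``direction='ge'`` means scores at or above the cutoff predict the
    event; ``'le'`` the reverse (used for protective markers such as mean
    ADC). The AUC is the Mann-Whitney concordance of the oriented score
    (ties count one half). Candidate cutoffs are the observed score
    values; Youden-J ties resolve toward higher specificity, then toward
    the more conservative cutoff.
    """
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    oriented = s if direction == "ge" else -s
    auc = float(roc_auc_score(y, oriented))

    # candidate thresholds sit midway between adjacent distinct scores
    # (plus the all-positive extreme), so a separable boundary case is
    # classified correctly on either side of the gap
    v = np.unique(s)
    if v.size > 1:
        mid = (v[:-1] + v[1:]) / 2.0
        candidates = np.concatenate([[v[0]], mid]) if direction == "ge" else np.concatenate([mid, [v[-1]]])
    else:
        candidates = v

    best = None
    for c in candidates:
        pred = s >= c if direction == "ge" else s <= c
        sens = float((pred & y).sum() / y.sum())
        spec = float((~pred & ~y).sum() / (~y).sum())
        j = sens + spec - 1.0
        conservative = c if direction == "ge" else -c
        key = (j, spec, conservative)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, float((pred == y).mean()))
    _, cutoff, sens, spec, acc = best
    return ROCResult(
        auc=auc, cutoff=float(cutoff), direction=direction,
        sensitivity=sens, specificity=spec, accuracy=acc,
    )


def loocv_threshold(
    cohort: pd.DataFrame,
    predictor: str,
    direction: str = "ge",
    outcome_col: str = "doc_within_3y",
    fixed_cutoff: Optional[float] = None,
) -> CVResult:
    """Leave-one-out cross-validation of the single-threshold classifier.

    Each patient is classified by a cutoff chosen on the remaining n-1
    patients via the Youden rule (or by ``fixed_cutoff`` when given,
    reproducing the fixed-threshold variant). Training folds that lose an
    outcome class fall back to the majority class and are flagged.
    """
    s = cohort[predictor].to_numpy(dtype=float)
    y = cohort[outcome_col].to_numpy().astype(bool)
    n = len(s)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 patients")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    preds = np.zeros(n, dtype=bool)
    cuts = np.full(n, np.nan)
    degenerate = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        ytr = y[keep]
        if ytr.all() or not ytr.any():
            degenerate.append(i)
            preds[i] = ytr.mean() >= 0.5
            log.warning("LOOCV fold %d: single-class training set; majority vote", i)
            continue
        if fixed_cutoff is not None:
            c = fixed_cutoff
        else:
            c = roc_analysis(s[keep], ytr, direction).cutoff
        cuts[i] = c
        preds[i] = s[i] >= c if direction == "ge" else s[i] <= c
    return CVResult(
        fold_predictions=preds,
        fold_cutoffs=cuts,
        accuracy=float((preds == y).mean()),
        degenerate_folds=degenerate,
    )
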