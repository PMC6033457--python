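"""Cohort I/O, analysis-report assembly and pipeline orchestration.

The cohort CSV dialect: one header row, UTF-8, '.' decimal. ADC columns
(``mean_e3``, ``median_e3``) are stored in x10^-3 mm^2/s; pADC columns
in percent. ``run_pipeline`` chains simulate -> group stats -> Cox ->
logistic/ROC -> LOOCV, persisting each stage's output so every reported
number can be recomputed from the persisted artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .effect_stats import GroupSummary, cohens_d, fisher_exact_2xk, welch_test
from .exceptions import EmptyCohortError, PipelineStageError, SchemaError
from .prognostic_models import (
    check_ph_assumption,
    fit_univariate_cox,
    fit_univariate_logistic,
    loocv_threshold,
    roc_analysis,
)
from .synthetic_cohort import CohortConfig, generate_cohort

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_cohort_csv",
    "write_cohort_csv",
    "group_stats_table",
    "prognostic_tables",
    "crossval_summary",
    "run_pipeline",
    "write_report",
    "report_text",
]

#: cohort CSV column dictionary (name -> short description)
COHORT_COLUMNS = {
    "patient_id": "unique identifier",
    "group": "outcome group label (doc / survived)",
    "mean_e3": "ROI ADC mean, x10^-3 mm^2/s",
    "median_e3": "ROI ADC median, x10^-3 mm^2/s",
    "padc_xlow": "% tumor area with ADC < 0.6 x10^-3 mm^2/s",
    "padc_low": "% tumor area with 0.6 <= ADC < 1.2",
    "padc_int": "% tumor area with 1.2 <= ADC < 1.8",
    "padc_high": "% tumor area with ADC >= 1.8",
    "skewness": "ROI ADC skewness (population moments)",
    "kurtosis": "ROI ADC excess kurtosis (population moments)",
    "age": "age at surgery, years",
    "age_ge_60": "binary: age >= 60",
    "t_grade": "ordinal T stage (Tis/T2/T3/T4 -> 0-3)",
    "n_grade": "ordinal N stage (N0/N1/N2b/N3b -> 0-3)",
    "m_grade": "ordinal M stage (M0/M1 -> 0-1)",
    "margin_positive": "binary: positive surgical margin",
    "additional_treatment": "binary: adjuvant chemo/radiotherapy given",
    "followup_months": "follow-up or time to death, months",
    "doc_event": "binary: died of cancer during follow-up",
    "doc_within_3y": "binary: died of cancer within 3 years",
}

_REQUIRED = [c for c in COHORT_COLUMNS if c not in ("group",)]

# predictor -> (unit scale in column units, printed unit, ROC direction)
# ADC mean/median HRs are reported per 1x10^-4 mm^2/s (= 0.1 column
# units); binary/ordinal predictors per grade or category.
PREDICTOR_SPECS: dict[str, tuple[float, str, str]] = {
    "mean_e3": (0.1, "1 x 10^-4 mm^2/s", "le"),
    "median_e3": (0.1, "1 x 10^-4 mm^2/s", "le"),
    "padc_xlow": (1.0, "1%", "ge"),
    "padc_low": (1.0, "1%", "le"),
    "padc_int": (1.0, "1%", "le"),
    "padc_high": (1.0, "1%", "le"),
    "skewness": (1.0, "1", "ge"),
    "kurtosis": (1.0, "1", "ge"),
    "t_grade": (1.0, "1 grade", "ge"),
    "n_grade": (1.0, "1 grade", "ge"),
    "m_grade": (1.0, "1 grade", "ge"),
    "age_ge_60": (1.0, ">=60 vs <60 years", "ge"),
    "margin_positive": (1.0, "positive vs negative", "ge"),
    "additional_treatment": (1.0, "performed vs none", "ge"),
}

_ADC_PARAMS = [
    "mean_e3", "median_e3", "padc_xlow", "padc_low", "padc_int", "padc_high",
    "skewness", "kurtosis",
]
_CATEGORICALS = {
    "t_grade": 4, "n_grade": 4, "m_grade": 2,
    "margin_positive": 2, "additional_treatment": 2,
}


@dataclass
class RunConfig:
    """End-to-end run settings; all randomness flows from ``seed``."""

    seed: int
    out_dir: Optional[str] = None
    cohort_csv: Optional[str] = None  # when given, the simulate stage is skipped
    n_doc: int = 6
    n_survived: int = 14
    stages: tuple[str, ...] = ("simulate", "groupstats", "analyze", "crossval")
    cv_predictor: str = "padc_xlow"
    cv_direction: str = "ge"
    cv_fixed_cutoff: Optional[float] = None
    exclude_extreme_slices: bool = False
    cox_ties: str = "efron"
    padc_sum_tolerance: float = 0.5


# ---------------------------------------------------------------------------
# cohort CSV


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort table; see ``COHORT_COLUMNS``."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise EmptyCohortError(f"{path} is empty")
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyCohortError(f"{path} contains no patient rows")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    padc_sum = df[["padc_xlow", "padc_low", "padc_int", "padc_high"]].sum(axis=1)
    bad = np.abs(padc_sum - 100.0) > 0.5
    if bad.any():
        warnings.warn(
            f"pADC columns of {int(bad.sum())} row(s) do not sum to 100 "
            f"(max deviation {float(np.abs(padc_sum - 100).max()):.2f})",
            stacklevel=2,
        )
    if (df["followup_months"] <= 0).any():
        raise SchemaError("followup_months must be positive")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report sections


def _group_frames(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    ev = df["doc_within_3y"].astype(bool)
    return df[ev], df[~ev]


def group_stats_table(df: pd.DataFrame) -> dict:
    """Outcome-group comparison: Welch + Cohen's d per continuous
    parameter, Freeman-Halton exact test per categorical."""
    doc, surv = _group_frames(df)
    out: dict = {"continuous": {}, "categorical": {}}
    for col in _ADC_PARAMS + ["age"]:
        g1 = GroupSummary.from_values(doc[col])
        g2 = GroupSummary.from_values(surv[col])
        w = welch_test(g1, g2)
        es = cohens_d(g1, g2)
        out["continuous"][col] = {
            "doc": asdict(g1),
            "survived": asdict(g2),
            "welch_t": w.t,
            "welch_df": w.df,
            "welch_p": w.p,
            "cohens_d": es.d,
            "cohens_d_abs": es.magnitude,
        }
    for col, k in _CATEGORICALS.items():
        counts = np.zeros((2, k), dtype=int)
        for j in range(k):
            counts[0, j] = int((doc[col] == j).sum())
            counts[1, j] = int((surv[col] == j).sum())
        keep = counts.sum(axis=0) > 0
        table = counts[:, keep] if keep.sum() >= 2 else counts
        out["categorical"][col] = {
            "counts": counts.tolist(),
            "fisher_p": fisher_exact_2xk(table),
        }
    return out


def prognostic_tables(df: pd.DataFrame, ties: str = "efron") -> dict:
    """Per-predictor univariate Cox and logistic/ROC result tables.

    Predictors failing the proportional-hazards diagnostic are excluded
    from the Cox table (marker retained); degenerate predictors carry an
    explicit skipped-with-reason marker and the run continues.
    """
    work = df.copy()
    cox: dict = {}
    logistic: dict = {}
    for pred, (scale, unit, direction) in PREDICTOR_SPECS.items():
        # --- Cox
        try:
            fit = fit_univariate_cox(work, pred, unit_scale=scale, ties=ties)
            ph = check_ph_assumption(fit, work, pred)
            if ph.defined and ph.excluded:
                cox[pred] = {
                    "skipped": "proportional-hazards assumption violated",
                    "ph_p": ph.p,
                    "unit": unit,
                }
            else:
                cox[pred] = {
                    "hazard_ratio": fit.hazard_ratio,
                    "ci95": list(fit.ci95),
                    "p": fit.p,
                    "unit": unit,
                    "converged": fit.converged,
                    "ph_p": ph.p if ph.defined else None,
                }
        except Exception as err:
            cox[pred] = {"skipped": str(err), "unit": unit}
        # --- logistic (+ ROC when significant)
        try:
            lfit = fit_univariate_logistic(work, pred, unit_scale=scale)
            entry = {
                "odds_ratio": lfit.odds_ratio,
                "ci95": list(lfit.ci95),
                "p": lfit.p,
                "unit": unit,
                "converged": lfit.converged,
            }
            if lfit.converged and np.isfinite(lfit.p) and lfit.p < 0.05:
                direction_fit = "ge" if lfit.beta > 0 else "le"
                roc = roc_analysis(
                    work[pred].to_numpy(float),
                    work["doc_within_3y"].to_numpy(),
                    direction_fit,
                )
                entry["roc"] = {
                    "auc": roc.auc,
                    "cutoff": roc.cutoff,
                    "direction": roc.direction,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                    "accuracy": roc.accuracy,
                }
            logistic[pred] = entry
        except Exception as err:
            logistic[pred] = {"skipped": str(err), "unit": unit}
    return {"cox": cox, "logistic_roc": logistic}


def crossval_summary(
    df: pd.DataFrame,
    predictor: str = "padc_xlow",
    direction: str = "ge",
    fixed_cutoff: Optional[float] = None,
) -> dict:
    cv = loocv_threshold(df, predictor, direction, fixed_cutoff=fixed_cutoff)
    return {
        "predictor": predictor,
        "direction": direction,
        "accuracy": cv.accuracy,
        "fold_cutoffs": [None if np.isnan(c) else float(c) for c in cv.fold_cutoffs],
        "fold_predictions": cv.fold_predictions.astype(int).tolist(),
        "degenerate_folds": cv.degenerate_folds,
    }


# ---------------------------------------------------------------------------
# orchestration


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, default=str)


def _hash(obj) -> str:
    return hashlib.sha256(_canonical_json(obj).encode()).hexdigest()[:16]


def _subtype_summary(df: pd.DataFrame) -> dict:
    """Per-group mean +/- sd summary of histogram parameters."""
    out: dict = {}
    for group, sub in df.groupby("group" if "group" in df.columns else "doc_within_3y"):
        entry = {}
        for col in _ADC_PARAMS:
            vals = sub[col].to_numpy(float)
            entry[col] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
                "n": len(vals),
            }
        out[str(group)] = entry
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and assemble the report.

    Every stage's output is persisted under ``config.out_dir`` (when
    set) before the next stage runs; a failure aborts with the stage
    name. Identical config + seed reproduce an identical report.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": _hash(asdict(config)),
            "version": __version__,
        }
    }

    def persist(name: str, payload) -> None:
        if out_dir:
            with open(out_dir / name, "w") as fh:
                if isinstance(payload, pd.DataFrame):
                    payload.to_csv(fh, index=False)
                else:
                    json.dump(payload, fh, indent=1, sort_keys=True, default=str)

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as err:
            raise PipelineStageError(name, str(err)) from err
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result

    if "simulate" in config.stages and config.cohort_csv is None:
        cohort = stage(
            "simulate",
            lambda: generate_cohort(
                CohortConfig(seed=config.seed, n_doc=config.n_doc, n_survived=config.n_survived)
            ),
        )
        persist("cohort.csv", cohort)
    else:
        cohort = stage("load", lambda: read_cohort_csv(config.cohort_csv))

    report["group_summary"] = stage("summary", lambda: _subtype_summary(cohort))
    persist("group_summary.json", report["group_summary"])

    if "groupstats" in config.stages:
        report["group_comparison"] = stage("groupstats", lambda: group_stats_table(cohort))
        persist("group_comparison.json", report["group_comparison"])

    if "analyze" in config.stages:
        tables = stage("analyze", lambda: prognostic_tables(cohort, ties=config.cox_ties))
        report["cox"] = tables["cox"]
        report["logistic_roc"] = tables["logistic_roc"]
        persist("prognostic_tables.json", tables)

    if "crossval" in config.stages:
        report["crossval"] = stage(
            "crossval",
            lambda: crossval_summary(
                cohort,
                config.cv_predictor,
                config.cv_direction,
                fixed_cutoff=config.cv_fixed_cutoff,
            ),
        )
        persist("crossval.json", report["crossval"])

    report["provenance"]["report_hash"] = _hash(
        {k: v for k, v in report.items() if k != "provenance"}
    )
    if out_dir:
        write_report(report, out_dir / "report.json")
        (out_dir / "report.txt").write_text(report_text(report))
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)


def report_text(report: dict) -> str:
    """Fixed-width human rendering of the four report sections."""
    lines: list[str] = []

    def hdr(title):
        lines.extend(["", title, "-" * len(title)])

    if "group_summary" in report:
        hdr("Histogram parameters by group (mean +/- sd)")
        for group, entry in report["group_summary"].items():
            lines.append(f"[{group}]")
            for col, st in entry.items():
                sd = f" +/- {st['sd']:.2f}" if st["sd"] is not None else ""
                lines.append(f"  {col:<12} {st['mean']:8.2f}{sd}  (n={st['n']})")
    if "group_comparison" in report:
        hdr("Group comparison (died of cancer vs survived)")
        for col, row in report["group_comparison"]["continuous"].items():
            lines.append(
                f"  {col:<12} doc {row['doc']['mean']:7.2f} +/- {row['doc']['sd']:5.2f}"
                f"  surv {row['survived']['mean']:7.2f} +/- {row['survived']['sd']:5.2f}"
                f"  Welch p={row['welch_p']:.3f}  |d|={row['cohens_d_abs']:.2f}"
            )
        for col, row in report["group_comparison"]["categorical"].items():
            lines.append(f"  {col:<22} Fisher exact p={row['fisher_p']:.3f}")
    if "cox" in report:
        hdr("Univariate Cox proportional hazards")
        for pred, row in report["cox"].items():
            if "skipped" in row:
                lines.append(f"  {pred:<22} skipped: {row['skipped']}")
            else:
                lo, hi = row["ci95"]
                lines.append(
                    f"  {pred:<22} HR {row['hazard_ratio']:6.2f} per {row['unit']:<18}"
                    f" CI [{lo:6.3f}, {hi:7.3f}]  p={row['p']:.3f}"
                )
    if "logistic_roc" in report:
        hdr("Univariate logistic regression / ROC")
        for pred, row in report["logistic_roc"].items():
            if "skipped" in row:
                lines.append(f"  {pred:<22} skipped: {row['skipped']}")
                continue
            base = (
                f"  {pred:<22} OR {row['odds_ratio']:6.2f} per {row['unit']:<18}"
                f" p={row['p']:.3f}" if np.isfinite(row["p"]) else
                f"  {pred:<22} OR not estimable (separation)"
            )
            if "roc" in row:
                r = row["roc"]
                sign = ">=" if r["direction"] == "ge" else "<="
                base += (
                    f"  AUC={r['auc']:.3f} cutoff {sign} {r['cutoff']:.3g}"
                    f" sens={r['sensitivity']:.2f} spec={r['specificity']:.2f}"
                    f" acc={r['accuracy']:.2f}"
                )
            lines.append(base)
    if "crossval" in report:
        hdr("Leave-one-out cross-validation")
        cv = report["crossval"]
        lines.append(
            f"  predictor {cv['predictor']} ({cv['direction']}):"
            f" accuracy {cv['accuracy']:.2f}"
        )
    lines.append("")
    return "\n".join(lines)
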