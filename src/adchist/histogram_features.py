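"""ROI ADC histogram profiling.

A tumor ROI's pooled ADC values are summarized by five histogram
parameters: mean, median, skewness, excess kurtosis and the four-bin
pADC percentages (fraction of tumor voxels in named diffusion ranges).

Skewness and kurtosis follow the population-moment definitions
``E(x - mu)^3 / sigma^3`` and ``E(x - mu)^4 / sigma^4 - 3`` (denominator
N, no small-sample correction), so a normal sample tends to (0, 0).
pADC bins are closed on the left: a value exactly at a threshold falls
in the upper bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateROIError, UndefinedMomentsError

__all__ = [
    "BinScheme",
    "DEFAULT_BINS",
    "MomentStatistics",
    "ADCHistogramProfile",
    "moment_statistics",
    "padc_fractions",
    "profile",
    "summarize_by_group",
    "profile_to_row",
    "profiles_to_frame",
    "PROFILE_COLUMNS",
]


@dataclass(frozen=True)
class BinScheme:
    """ADC categorisation thresholds (mm^2/s) and bin labels.

    Defaults to the clinical four-category scheme: extremely low
    (< 0.6), low [0.6, 1.2), intermediate [1.2, 1.8) and high (>= 1.8),
    in units of x10^-3 mm^2/s.
    """

    thresholds: tuple[float, ...] = (0.6e-3, 1.2e-3, 1.8e-3)
    labels: tuple[str, ...] = ("extremely_low", "low", "intermediate", "high")

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.labels) != t.size + 1:
            raise ValueError("label count must equal threshold count + 1")

    @property
    def n_bins(self) -> int:
        return len(self.labels)


DEFAULT_BINS = BinScheme()


class MomentStatistics(NamedTuple):
    mean: float
    median: float
    skewness: float
    kurtosis: float


@dataclass
class ADCHistogramProfile:
    """Five-parameter histogram descriptor of one tumor ROI.

    ``mean``/``median`` are in mm^2/s; ``padc`` holds per-bin percentages
    summing to 100. ``moments_defined`` is False when skewness/kurtosis
    could not be computed (fewer than two values or zero spread).
    """

    mean: float
    median: float
    skewness: float
    kurtosis: float
    padc: np.ndarray
    n_voxels: int
    moments_defined: bool = True
    bins: BinScheme = DEFAULT_BINS


def moment_statistics(values: Sequence[float]) -> MomentStatistics:
    """Mean, median and population-moment skewness / excess kurtosis.

    Raises
    ------
    ValueError
        If fewer than two values are supplied.
    UndefinedMomentsError
        If the vector is constant (sigma = 0).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("moments need at least 2 values")
    if np.ptp(x) == 0:
        raise UndefinedMomentsError(
            f"constant ADC vector (value {x[0]:g}); skewness/kurtosis undefined"
        )
    skew = float(sps.skew(x, bias=True))
    kurt = float(sps.kurtosis(x, fisher=True, bias=True))
    return MomentStatistics(float(x.mean()), float(np.median(x)), skew, kurt)


def padc_fractions(values: Sequence[float], bins: BinScheme = DEFAULT_BINS) -> np.ndarray:
    """Percentage of values per ADC bin, intervals closed on the left.

    Bin membership: (-inf, t1), [t1, t2), ..., [tk, inf). Returns
    percentages (100 * count / total) summing to 100.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise DegenerateROIError("cannot bin an empty ADC vector")
    idx = np.searchsorted(np.asarray(bins.thresholds), x, side="right")
    counts = np.bincount(idx, minlength=bins.n_bins)
    return 100.0 * counts / x.size


def profile(values: Sequence[float], bins: BinScheme = DEFAULT_BINS) -> ADCHistogramProfile:
    """Bundle moment statistics and pADC fractions into one profile.

    A singleton or constant vector yields a profile with
    ``moments_defined = False`` (NaN skewness/kurtosis); mean, median and
    pADC are always computed.
    """
    x = np.asarray(values, dtype=float).ravel()
    padc = padc_fractions(x, bins)
    try:
        m = moment_statistics(x)
        return ADCHistogramProfile(
            mean=m.mean, median=m.median, skewness=m.skewness, kurtosis=m.kurtosis,
            padc=padc, n_voxels=x.size, moments_defined=True, bins=bins,
        )
    except (ValueError, UndefinedMomentsError):
        return ADCHistogramProfile(
            mean=float(x.mean()), median=float(np.median(x)),
            skewness=float("nan"), kurtosis=float("nan"),
            padc=padc, n_voxels=x.size, moments_defined=False, bins=bins,
        )


#: Column dictionary of the per-patient profile CSV. ADC columns are in
#: x10^-3 mm^2/s, pADC columns in percent.
PROFILE_COLUMNS = (
    "patient_id", "n_voxels", "mean_e3", "median_e3", "skewness", "kurtosis",
    "padc_xlow", "padc_low", "padc_int", "padc_high",
)


def profile_to_row(prof: ADCHistogramProfile, patient_id) -> dict:
    """Serialize a profile to one CSV row (ADC rescaled to x10^-3 mm^2/s)."""
    return {
        "patient_id": patient_id,
        "n_voxels": prof.n_voxels,
        "mean_e3": prof.mean * 1e3,
        "median_e3": prof.median * 1e3,
        "skewness": prof.skewness,
        "kurtosis": prof.kurtosis,
        "padc_xlow": prof.padc[0],
        "padc_low": prof.padc[1],
        "padc_int": prof.padc[2],
        "padc_high": prof.padc[3],
    }


def profiles_to_frame(profiles: Iterable[ADCHistogramProfile], ids: Iterable) -> pd.DataFrame:
    return pd.DataFrame([profile_to_row(p, i) for p, i in zip(profiles, ids)])


def summarize_by_group(
    profiles: Sequence[ADCHistogramProfile],
    groups: Sequence,
) -> pd.DataFrame:
    """Per-group mean +/- sd of each profile field (long format).

    The standard deviation is the sample (N-1) sd; groups of size one
    report sd as NaN (a single case prints no +/-). ADC fields are
    reported in x10^-3 mm^2/s, matching the conventional table layout.
    """
    if len(profiles) != len(groups):
        raise ValueError("profiles and groups must align")
    frame = profiles_to_frame(profiles, range(len(profiles)))
    frame["group"] = list(groups)
    fields = [c for c in PROFILE_COLUMNS if c not in ("patient_id", "n_voxels")]
    rows = []
    for group, sub in frame.groupby("group", sort=False):
        for f in fields:
            vals = sub[f].to_numpy(dtype=float)
            rows.append(
                {
                    "group": group,
                    "parameter": f,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)
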