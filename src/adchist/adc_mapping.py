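"""Voxel-wise apparent diffusion coefficient (ADC) mapping.

The ADC quantifies hindered water diffusion in tissue. Under the
mono-exponential decay model ``S(b) = S0 * exp(-b * ADC)``, two
diffusion-weighted acquisitions at b-values ``b_low < b_high`` determine
the coefficient voxel-wise as::

    ADC = ln(S_low / S_high) / (b_high - b_low)

The canonical internal unit is mm^2/s; reporting layers rescale to the
conventional x10^-3 mm^2/s. Voxels with a nonpositive signal at either
b-value cannot be log-transformed and are flagged invalid rather than
clamped, so that fabricated extreme values never leak into histogram
bins. Negative ADC estimates (noise inverting the signal ratio) are kept
— the lowest histogram bin is unbounded below — but counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateROIError, MissingBValueError

log = logging.getLogger(__name__)

__all__ = [
    "DWIVolumeSet",
    "ADCMap",
    "ROIMask",
    "ROIExtraction",
    "compute_adc_map",
    "extract_roi_values",
]


@dataclass(frozen=True)
class DWIVolumeSet:
    """Co-registered diffusion-weighted signal volumes keyed by b-value.

    Parameters
    ----------
    volumes
        Mapping b-value (s/mm^2) -> 3-D signal array (arbitrary units).
    voxel_size
        In-plane and through-plane voxel dimensions in mm.
    slice_gap
        Inter-slice gap in mm.
    """

    volumes: dict[float, np.ndarray]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    slice_gap: float = 0.0

    def __post_init__(self):
        if len(self.volumes) < 2:
            raise ValueError("a DWIVolumeSet needs at least 2 distinct b-values")
        shapes = {np.asarray(v).shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError(f"all signal volumes must share one shape, got {shapes}")
        for b, vol in self.volumes.items():
            if b < 0:
                raise ValueError(f"negative b-value {b}")
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"non-finite signal values in b={b} volume")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.volumes.values())).shape

    @property
    def b_values(self) -> tuple[float, ...]:
        return tuple(sorted(self.volumes))


@dataclass
class ADCMap:
    """Voxel-wise diffusion coefficients (mm^2/s) with a validity mask.

    ``valid`` marks voxels where the two-point log-ratio was computable;
    ``n_negative`` counts valid voxels whose ADC came out negative.
    """

    values: np.ndarray
    valid: np.ndarray
    n_negative: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid arrays must share a shape")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("valid voxels must carry finite ADC values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class ROIMask:
    """Binary tumor region of interest aligned to an ADC map."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values) != 0
        if not self.values.any():
            raise ValueError("ROI mask must contain at least one voxel")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ROIMask":
        """Build a mask from any array; nonzero means inside the ROI."""
        return cls(values=np.asarray(arr) != 0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class ROIExtraction:
    """Pooled ADC values of an ROI plus bookkeeping on what was dropped."""

    values: np.ndarray
    n_invalid: int
    slices_used: list = field(default_factory=list)
    slices_excluded: list = field(default_factory=list)


def compute_adc_map(dwi: DWIVolumeSet, b_low: float, b_high: float) -> ADCMap:
    """Two-point mono-exponential ADC map from signal volumes at two b-values.

    Parameters
    ----------
    dwi
        Signal volumes; must contain both requested b-values.
    b_low, b_high
        Diffusion weightings in s/mm^2 with ``b_high > b_low``.

    Returns
    -------
    ADCMap
        ``values[v] = ln(S_low[v]/S_high[v]) / (b_high - b_low)`` wherever
        both signals are strictly positive; other voxels are invalid (NaN).

    Raises
    ------
    MissingBValueError
        If either b-value has no volume in ``dwi``.
    ValueError
        If ``b_high <= b_low``.
    """
    for b in (b_low, b_high):
        if b not in dwi.volumes:
            raise MissingBValueError(
                f"b={b} s/mm^2 not acquired (available: {dwi.b_values})"
            )
    if b_high <= b_low:
        raise ValueError(f"b_high ({b_high}) must exceed b_low ({b_low})")

    s_low = np.asarray(dwi.volumes[b_low], dtype=float)
    s_high = np.asarray(dwi.volumes[b_high], dtype=float)
    valid = (s_low > 0) & (s_high > 0)

    values = np.full(s_low.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[valid] = np.log(s_low[valid] / s_high[valid]) / (b_high - b_low)
    n_negative = int(np.count_nonzero(values[valid] < 0))
    if n_negative:
        log.info("ADC map: %d valid voxels with negative ADC retained", n_negative)
    return ADCMap(values=values, valid=valid, n_negative=n_negative)


def extract_roi_values(
    adc: ADCMap,
    roi: ROIMask,
    exclude_extreme_slices: bool = False,
    slice_axis: int = -1,
) -> ROIExtraction:
    """Pool valid ADC values over the ROI, optionally dropping the tumor poles.

    When ``exclude_extreme_slices`` is set and the ROI spans at least three
    slices along ``slice_axis``, the first and last ROI-bearing slices are
    dropped (partial-volume guard at the tumor poles). For ROIs spanning one
    or two slices the flag is ignored with a logged warning.

    Raises
    ------
    ValueError
        If shapes do not match.
    DegenerateROIError
        If no valid voxel survives masking and slice exclusion.
    """
    if adc.shape != roi.shape:
        raise ValueError(f"shape mismatch: ADC {adc.shape} vs ROI {roi.shape}")

    axis = slice_axis % adc.values.ndim
    mask = roi.values.copy()
    other_axes = tuple(i for i in range(mask.ndim) if i != axis)
    roi_slices = [int(i) for i in np.nonzero(mask.any(axis=other_axes))[0]]

    excluded: list[int] = []
    if exclude_extreme_slices:
        if len(roi_slices) >= 3:
            excluded = [roi_slices[0], roi_slices[-1]]
            for idx in excluded:
                sl = [slice(None)] * mask.ndim
                sl[axis] = idx
                mask[tuple(sl)] = False
        else:
            log.warning(
                "ROI spans only %d slice(s); extreme-slice exclusion ignored",
                len(roi_slices),
            )
    used = [s for s in roi_slices if s not in excluded]

    selected = mask & adc.valid
    n_invalid = int(np.count_nonzero(mask & ~adc.valid))
    values = adc.values[selected]
    if values.size == 0:
        raise DegenerateROIError(
            "no valid ADC values remain in the ROI after filtering"
        )
    return ROIExtraction(
        values=values, n_invalid=n_invalid, slices_used=used, slices_excluded=excluded
    )
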