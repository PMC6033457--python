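"""Thin NIfTI-1 helpers (nibabel-backed) used by the CLI verbs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .adc_mapping import ADCMap, ROIMask

__all__ = ["load_volume", "save_volume", "load_mask", "save_adc_map", "load_adc_map"]


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def save_volume(arr: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), str(path))


def load_mask(path) -> ROIMask:
    """Any nonzero voxel counts as inside the ROI."""
    return ROIMask.from_array(load_volume(path))


def save_adc_map(adc: ADCMap, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Invalid voxels are stored as NaN; validity is recoverable on load."""
    out = np.where(adc.valid, adc.values, np.nan)
    save_volume(out, path, voxel_size)


def load_adc_map(path) -> ADCMap:
    vals = load_volume(path)
    valid = np.isfinite(vals)
    return ADCMap(values=vals, valid=valid, n_negative=int((vals[valid] < 0).sum()))
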