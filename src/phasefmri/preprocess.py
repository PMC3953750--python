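"""Slice-timing correction, Gaussian and normalized-averaging smoothing,
EPI segmentation and registration-based skullstripping.

Normalized averaging computes (v.c * f) / (c * f) with a separable Gaussian
f and a certainty map c (the brain mask): voxels outside the mask then never
leak into smoothed in-mask values, avoiding edge darkening at the brain
boundary.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .io import Volume, FmriSeries
from . import register_linear as rl

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass
class SliceTimingSpec:
    """Acquisition times (seconds within the TR) per slice, plus the
    reference slice (default: the middle slice)."""

    slice_times: np.ndarray
    repetition_time: float
    reference: int | None = None

    def __post_init__(self) -> None:
        self.slice_times = np.asarray(self.slice_times, dtype=np.float64)
        if np.any(self.slice_times < 0) or np.any(self.slice_times >= self.repetition_time):
            raise ValueError("slice times must lie in [0, TR)")
        if self.reference is None:
            self.reference = len(self.slice_times) // 2

    @classmethod
    def from_order(cls, n_slices: int, repetition_time: float,
                   order: str = "ascending") -> "SliceTimingSpec":
        dt = repetition_time / n_slices
        if order == "ascending":
            seq = np.arange(n_slices)
        elif order == "descending":
            seq = np.arange(n_slices)[::-1]
        elif order == "interleaved":
            seq = np.concatenate([np.arange(0, n_slices, 2),
                                  np.arange(1, n_slices, 2)])
        else:
            raise ValueError(f"unknown slice order {order!r}")
        times = np.empty(n_slices)
        times[seq] = np.arange(n_slices) * dt
        return cls(times, repetition_time)


def _catmull_rom(series: np.ndarray, shift: float) -> np.ndarray:
    """Resample ``series`` (last axis = time) at index t + shift with the
    Catmull-Rom cubic kernel, clamped at the edges."""
    T = series.shape[-1]
    pos = np.arange(T) + shift
    i1 = np.floor(pos).astype(int)
    u = pos - i1
    idx = np.clip(np.stack([i1 - 1, i1, i1 + 1, i1 + 2]), 0, T - 1)
    p0, p1, p2, p3 = (series[..., idx[k]] for k in range(4))
    u = u[None, :] if series.ndim > 1 else u
    return 0.5 * (2.0 * p1 + (-p0 + p2) * u
                  + (2.0 * p0 - 5.0 * p1 + 4.0 * p2 - p3) * u ** 2
                  + (-p0 + 3.0 * p1 - 3.0 * p2 + p3) * u ** 3)


def slice_timing_correct(series: FmriSeries, spec: SliceTimingSpec) -> FmriSeries:
    """Resample every slice's time series to the reference slice's
    acquisition time (Catmull-Rom cubic interpolation in time).

    The reference slice is returned bitwise unchanged; series length is
    preserved with clamped-edge boundary handling.
    """
    if series.n_volumes < 4:
        raise ValueError("slice timing needs >= 4 time points for cubic support")
    n_slices = series.spatial_shape[2]
    if len(spec.slice_times) != n_slices:
        raise ValueError(
            f"{len(spec.slice_times)} slice times for {n_slices} slices")
    t_ref = spec.slice_times[spec.reference]
    out = np.empty_like(series.data)
    for z in range(n_slices):
        shift = (t_ref - spec.slice_times[z]) / series.repetition_time
        if shift == 0.0:
            out[:, :, z, :] = series.data[:, :, z, :]
            continue
        sl = series.data[:, :, z, :].reshape(-1, series.n_volumes)
        out[:, :, z, :] = _catmull_rom(sl, shift).reshape(
            series.spatial_shape[0], series.spatial_shape[1], series.n_volumes)
    return FmriSeries(out, repetition_time=series.repetition_time,
                      voxel_size=series.voxel_size, affine=series.affine.copy())


def _sigma_voxels(fwhm_mm: float, voxel_size) -> tuple[float, float, float]:
    return tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size)


def gaussian_smooth(volume: Volume, fwhm_mm: float, mode: str = "constant") -> Volume:
    """Cartesian-separable Gaussian smoothing; sigma = FWHM / (2 sqrt(2 ln 2))
    per axis in voxel units, kernel truncated at 4 sigma. Zero padding in the
    default mode shrinks values toward the borders (documented behaviour).
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume.like(volume.data.copy())
    sigma = _sigma_voxels(fwhm_mm, volume.voxel_size)
    out = ndimage.gaussian_filter(volume.data, sigma=sigma, mode=mode,
                                  truncate=4.0)
    return volume.like(out)


def smooth_normalized(volume: Volume, certainty: np.ndarray,
                      fwhm_mm: float) -> Volume:
    """Normalized averaging: (v.c * f) / (c * f) with the separable Gaussian.

    Certainty must lie in [0, 1]. Voxels where the smoothed certainty falls
    below 1e-6 are set to zero (counted in a warning).
    """
    certainty = np.asarray(certainty, dtype=np.float64)
    if certainty.shape != volume.shape:
        raise ValueError("certainty shape mismatch")
    if certainty.min() < 0 or certainty.max() > 1:
        raise ValueError("certainty must lie in [0, 1]")
    if fwhm_mm == 0:
        return volume.like(volume.data * (certainty > 0))
    sigma = _sigma_voxels(fwhm_mm, volume.voxel_size)
    num = ndimage.gaussian_filter(volume.data * certainty, sigma=sigma,
                                  mode="constant", truncate=4.0)
    den = ndimage.gaussian_filter(certainty, sigma=sigma, mode="constant",
                                  truncate=4.0)
    bad = den < 1e-6
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~bad)
    n_bad_inside = int(np.count_nonzero(bad & (certainty > 0)))
    if n_bad_inside:
        warnings.warn(f"{n_bad_inside} voxels with degenerate smoothed "
                      "certainty set to zero", RuntimeWarning, stacklevel=2)
    return volume.like(out)


def smooth_series(series: FmriSeries, fwhm_mm: float,
                  mask: np.ndarray | None = None) -> FmriSeries:
    """Smooth every volume of a series; with a mask, normalized averaging."""
    out = np.empty_like(series.data)
    for t in range(series.n_volumes):
        vol = series.volume(t)
        if mask is None:
            out[..., t] = gaussian_smooth(vol, fwhm_mm).data
        else:
            out[..., t] = smooth_normalized(vol, mask, fwhm_mm).data
    return FmriSeries(out, repetition_time=series.repetition_time,
                      voxel_size=series.voxel_size, affine=series.affine.copy())


def segment_epi(series: FmriSeries | Volume, volume_index: int = 0,
                smoothing_fwhm_mm: float = 4.0) -> Volume:
    """Brain mask from one fMRI volume: 4 mm 3D Gaussian smoothing, then a
    threshold at 90% of the smoothed volume's mean over all voxels.

    The rule is invariant to global intensity scaling. Border handling uses
    edge replication so a constant positive volume yields a full mask.
    """
    vol = series.volume(volume_index) if isinstance(series, FmriSeries) else series
    if not np.any(vol.data):
        raise ValueError("cannot segment an all-zero volume")
    smoothed = gaussian_smooth(vol, smoothing_fwhm_mm, mode="nearest")
    threshold = 0.9 * smoothed.data.mean()
    return vol.like((smoothed.data > threshold).astype(np.float64))


def skullstrip(t1: Volume, template_with_skull: Volume, template_brain: Volume,
               template_mask: Volume, scales: int = 2,
               iterations_per_scale: int = 10) -> Volume:
    """Two-pass registration-based skullstrip.

    Pass 1: affine-register the T1 to the with-skull template, inverse-
    transform the template brain mask into T1 space (nearest-neighbour then
    > 0.5 binarization) and multiply with the original T1. Pass 2: register
    the stripped T1 to the brain-only template and re-transform the mask
    with the new parameters, again multiplying the ORIGINAL T1.
    """
    def _mask_to_t1(params: rl.AffineParams) -> np.ndarray:
        moved = rl.apply_affine(template_mask.data, params.inverse(),
                                interpolation="nearest")
        return (moved > 0.5).astype(np.float64)

    params1, _ = rl.estimate_transform(template_with_skull.data, t1.data,
                                       model="affine", scales=scales,
                                       iterations_per_scale=iterations_per_scale)
    stripped1 = t1.data * _mask_to_t1(params1)
    params2, _ = rl.estimate_transform(template_brain.data, stripped1,
                                       model="affine", scales=scales,
                                       iterations_per_scale=iterations_per_scale)
    return t1.like(t1.data * _mask_to_t1(params2))
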