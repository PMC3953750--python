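"""Synthetic-data generators with known ground truth.

Every pipeline stage is testable without downloads: phantom T1-like volumes
with internal structure (so bandpass quadrature filters have edges and lines
to lock onto), rigidly transformed 4D series with recorded motion
parameters drawn N(0, 0.5) (voxels for translations, degrees for rotations),
optional intensity shading, and block-design activation series with AR
noise. Generators are pure functions of (parameters, seed).

These phantoms emulate geometry and noise statistics only — not MR physics
(no B0 distortion, spin history or physiological noise).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import Volume, FmriSeries
from .register_linear import AffineParams, apply_affine, compose_euler


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth serialized alongside every generated dataset."""

    seed: int
    transforms: np.ndarray | None = None      # T x 6: translations + degrees
    beta: np.ndarray | None = None            # per-voxel true effect
    rho: np.ndarray | None = None             # AR coefficients
    sigma2: float | None = None               # innovation variance
    activation_mask: np.ndarray | None = None
    brain_mask: np.ndarray | None = None
    shading: np.ndarray | None = None         # (offset, slope) per volume


def _ellipsoid(shape, semi_axes, center=None) -> np.ndarray:
    if center is None:
        center = [(n - 1) / 2.0 for n in shape]
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def make_phantom_volume(shape=(32, 32, 32), kind: str = "brain", seed: int = 0,
                        ) -> tuple[Volume, dict[str, np.ndarray]]:
    """Smooth ellipsoidal phantom with nested intensity structure and a
    smoothed noise texture; ``head_with_skull`` adds a bright shell, ``blob``
    is a cluster of smooth Gaussian bumps. Returns (volume, truth masks)."""
    shape = tuple(int(n) for n in shape)
    if any(n < 16 for n in shape):
        raise ValueError(f"phantom shape must be >= 16 per axis, got {shape}")
    if kind not in ("brain", "head_with_skull", "blob"):
        raise ValueError(f"unknown phantom kind {kind!r}")
    rng = np.random.default_rng(seed)
    data = np.zeros(shape)
    masks: dict[str, np.ndarray] = {}

    if kind == "blob":
        n_bumps = 6
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        for _ in range(n_bumps):
            center = [0.25 * n + 0.5 * n * rng.random() for n in shape]
            width = 0.06 * min(shape) + 0.08 * min(shape) * rng.random()
            amp = 400.0 + 800.0 * rng.random()
            r2 = sum(((g - c) / width) ** 2 for g, c in zip(grids, center))
            data += amp * np.exp(-r2 / 2.0)
        masks["brain"] = data > 50.0
        return Volume(data), masks

    # nested ellipsoids give strong edges; blobs and texture give the
    # bandpass filters internal lines to lock onto
    scale = 0.68 if kind == "head_with_skull" else 0.78
    semi = [scale * n / 2.0 * s for n, s in zip(shape, (1.0, 0.95, 0.9))]
    brain = _ellipsoid(shape, semi)
    data[brain] = 1000.0
    data[_ellipsoid(shape, [0.62 * a for a in semi])] = 700.0
    data[_ellipsoid(shape, [0.30 * a for a in semi])] = 1300.0
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    for _ in range(8):
        center = [n / 2.0 + (rng.random() - 0.5) * 0.5 * n for n in shape]
        width = 1.5 + 2.5 * rng.random()
        amp = (rng.random() - 0.5) * 800.0
        r2 = sum(((g - c) / width) ** 2 for g, c in zip(grids, center))
        data += amp * np.exp(-r2 / 2.0) * brain
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.2)
    data += 250.0 * (texture / texture.std()) * brain
    if kind == "head_with_skull":
        outer = _ellipsoid(shape, [1.18 * a for a in semi])
        shell = outer & ~_ellipsoid(shape, [1.08 * a for a in semi])
        data[shell] = 1600.0
        masks["skull"] = shell
    data = ndimage.gaussian_filter(data, sigma=1.0)
    data = np.clip(data, 0.0, None)
    masks["brain"] = brain
    return Volume(data), masks


def rigid_params(translation, rotation_deg) -> AffineParams:
    """Rigid transform from 3 translations (voxels) and 3 angles (degrees),
    in the module's Euler convention."""
    r = compose_euler(*np.radians(rotation_deg))
    return AffineParams.from_matrix(r, np.asarray(translation, dtype=float))


def make_motion_series(volume: Volume, T: int = 20, sigma: float = 0.5,
                       noise_pct: float = 1.0, shading: bool = False,
                       seed: int = 0) -> tuple[FmriSeries, SimulationTruth]:
    """4D series built by rigidly transforming one volume with transforms
    drawn N(0, sigma) per parameter (volume 0 untransformed), plus Gaussian
    white noise with s.d. = noise_pct% of the maximum intensity and an
    optional linear shading gradient increasing upwards."""
    if T < 2:
        raise ValueError("need T >= 2 volumes")
    rng = np.random.default_rng(seed)
    data = np.empty(volume.shape + (T,))
    transforms = np.zeros((T, 6))
    shade_coef = np.zeros((T, 2))
    zc = np.arange(volume.shape[2], dtype=float) - (volume.shape[2] - 1) / 2.0
    max_int = float(volume.data.max())
    data[..., 0] = volume.data
    for t in range(1, T):
        par6 = rng.normal(0.0, sigma, size=6) if sigma > 0 else np.zeros(6)
        transforms[t] = par6
        params = rigid_params(par6[:3], par6[3:])
        data[..., t] = apply_affine(volume.data, params.inverse())
    noise_sd = noise_pct / 100.0 * max_int
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    if shading:
        for t in range(T):
            offset = 0.05 * max_int
            slope = 0.30 * max_int / max(volume.shape[2], 1)
            shade_coef[t] = (offset, slope)
            data[..., t] += offset + slope * zc[None, None, :]
    series = FmriSeries(data, repetition_time=2.0, voxel_size=volume.voxel_size,
                        affine=volume.affine.copy())
    truth = SimulationTruth(seed=seed, transforms=transforms,
                            shading=shade_coef if shading else None)
    return series, truth


def boxcar_regressor(T: int, block_length: int = 10, start: int = 10) -> np.ndarray:
    """Alternating off/on boxcar, one column; fixtures-only convenience."""
    reg = np.zeros(T)
    t = start
    while t < T:
        reg[t:t + block_length] = 1.0
        t += 2 * block_length
    return reg


def gamma_hrf_regressor(T: int, block_length: int = 10, start: int = 10,
                        tr: float = 2.0, peak: float = 6.0,
                        fwhm: float = 5.2) -> np.ndarray:
    """Boxcar convolved with a single-gamma haemodynamic response;
    fixtures-only convenience (the analysis caller supplies regressors)."""
    box = boxcar_regressor(T, block_length, start)
    times = np.arange(0, 32.0, tr)
    a = (peak / fwhm) ** 2 * 8.0 * np.log(2.0)
    b = peak / a
    with np.errstate(divide="ignore"):
        hrf = (times / peak) ** a * np.exp(-(times - peak) / b)
    hrf[0] = 0.0
    hrf /= hrf.sum()
    out = np.convolve(box, hrf)[:T]
    return out


def _ar_is_stable(rho: np.ndarray) -> bool:
    poly = np.concatenate([[1.0], -np.asarray(rho, dtype=float)])
    if len(poly) == 1:
        return True
    roots = np.roots(poly[::-1])  # roots of 1 - sum rho_i z^i in z
    return bool(np.all(np.abs(roots) > 1.0)) if roots.size else True


def generate_ar_noise(shape_v: int, T: int, rho, sigma2: float,
                      rng: np.random.Generator) -> np.ndarray:
    """AR(p) noise (V, T) with innovation variance sigma2; burn-in discarded."""
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    if not _ar_is_stable(rho):
        raise ValueError(f"unstable AR coefficients {rho}")
    p = len(rho)
    burn = 10 * p + 50
    w = rng.normal(0.0, np.sqrt(sigma2), size=(shape_v, T + burn))
    eps = np.zeros_like(w)
    for t in range(T + burn):
        acc = w[:, t].copy()
        for i in range(1, p + 1):
            if t - i >= 0:
                acc += rho[i - 1] * eps[:, t - i]
        eps[:, t] = acc
    return eps[:, burn:]


def make_activation_fmri(shape=(16, 16, 16), T: int = 100,
                         task_regressors: np.ndarray | None = None,
                         beta_effect: float = 1.0, rho=(0.0,),
                         sigma2: float = 1.0, baseline: float = 100.0,
                         baseline_volume: Volume | None = None,
                         seed: int = 0) -> tuple[FmriSeries, SimulationTruth]:
    """Block-design activation series: y_t = baseline + X beta + AR noise per
    voxel, with the effect confined to an ellipsoidal ground-truth mask.

    ``baseline_volume`` replaces the flat baseline with a structured volume
    (e.g. a phantom) so registration stages have content to lock onto.
    """
    if T <= 20:
        raise ValueError("need T > 20 time points")
    shape = tuple(int(n) for n in shape)
    if baseline_volume is not None and baseline_volume.shape != shape:
        raise ValueError("baseline volume shape mismatch")
    rng = np.random.default_rng(seed)
    if task_regressors is None:
        task_regressors = boxcar_regressor(T)[:, None]
    task_regressors = np.atleast_2d(np.asarray(task_regressors, dtype=float))
    if task_regressors.shape[0] != T:
        task_regressors = task_regressors.T
    if task_regressors.shape[0] != T:
        raise ValueError("task regressor length mismatch")

    act_mask = _ellipsoid(shape, [0.18 * n for n in shape])
    beta_map = np.where(act_mask, beta_effect, 0.0)
    V = int(np.prod(shape))
    noise = generate_ar_noise(V, T, rho, sigma2, rng)
    signal = beta_map.reshape(V, 1) * task_regressors[:, 0][None, :]
    base = (baseline_volume.data.reshape(V, 1) if baseline_volume is not None
            else baseline)
    data = (base + signal + noise).reshape(shape + (T,))
    series = FmriSeries(data, repetition_time=2.0)
    truth = SimulationTruth(seed=seed, beta=beta_map,
                            rho=np.atleast_1d(np.asarray(rho, float)),
                            sigma2=sigma2, activation_mask=act_mask)
    return series, truth


def motion_error(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Total motion-parameter error: sqrt of the sum of squared differences
    over all time points and all 6 parameters."""
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError(f"shape mismatch {estimated.shape} vs {truth.shape}")
    return float(np.sqrt(np.sum((estimated - truth) ** 2)))
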