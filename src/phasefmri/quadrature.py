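"""Quadrature filter banks and local-phase quantities.

A quadrature filter is a complex-valued bandpass filter: its real part is
even-symmetric (a line detector) and its imaginary part odd-symmetric (an
edge detector). The argument of the filter response is the local phase,
which encodes the type of local structure independently of image intensity;
the magnitude acts as a certainty. Phase differences between two volumes,
per-filter phase gradients, and orientation-weighted structure tensors built
here drive both the affine and the Morphon registration algorithms.

Filters are designed in the frequency domain as a lognormal radial function

    R(w) = exp(-4 / (ln2 * B^2) * ln^2(w / w0))

times a directional factor (w_hat . n_hat)^2 on the half-space w_hat . n_hat > 0,
inverse-transformed, cropped to ``size``^3 and renormalized to unit response
at the tuning frequency. Defaults: center frequency w0 = pi/3 rad/sample,
bandwidth B = 2 octaves, size 7.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import fftconvolve

GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

#: Antipodal-unique icosahedron vertices (one per pair, last nonzero
#: coordinate non-negative), normalized below. Sum of outer products is 2*I.
_ICOSA_RAW = np.array([
    (0.0, 1.0, GOLDEN),
    (0.0, -1.0, GOLDEN),
    (1.0, GOLDEN, 0.0),
    (-1.0, GOLDEN, 0.0),
    (GOLDEN, 0.0, 1.0),
    (-GOLDEN, 0.0, 1.0),
])

_AXES_RAW = np.eye(3)


class ParameterError(ValueError):
    pass


@dataclasses.dataclass
class QuadratureFilterBank:
    """A set of complex 3D kernels with their tuning orientations."""

    kernels: list[np.ndarray]
    orientations: np.ndarray  # (N, 3) unit vectors
    center_frequency: float
    bandwidth: float

    @property
    def count(self) -> int:
        return len(self.kernels)

    @property
    def size(self) -> int:
        return self.kernels[0].shape[0]


@dataclasses.dataclass
class PhaseMatchField:
    """Per-voxel phase difference, certainty and (optional) phase gradient."""

    delta_phi: np.ndarray
    certainty: np.ndarray
    phase_gradient: np.ndarray | None = None  # (..., 3), radians/voxel


@dataclasses.dataclass
class TensorField:
    """Per-voxel symmetric 3x3 structure tensor, stored as 6 unique values
    in the order (xx, xy, xz, yy, yz, zz)."""

    components: np.ndarray  # (..., 6)

    def as_matrices(self) -> np.ndarray:
        """Expand to full (..., 3, 3) symmetric matrices."""
        c = self.components
        out = np.empty(c.shape[:-1] + (3, 3), dtype=c.dtype)
        out[..., 0, 0] = c[..., 0]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 1]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 2]
        out[..., 1, 1] = c[..., 3]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 4]
        out[..., 2, 2] = c[..., 5]
        return out


def _design_kernel(orientation: np.ndarray, size: int, center_frequency: float,
                   bandwidth: float, design_grid: int = 33) -> np.ndarray:
    """Sample the lognormal-directional frequency response on an odd grid,
    inverse-transform and crop the central ``size``^3 taps."""
    n = design_grid
    freqs = 2.0 * np.pi * np.fft.fftfreq(n)  # symmetric for odd n
    wx, wy, wz = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    wmag = np.sqrt(wx**2 + wy**2 + wz**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        radial = np.exp(-4.0 / (np.log(2.0) * bandwidth**2)
                        * np.log(wmag / center_frequency) ** 2)
    radial[wmag == 0] = 0.0
    proj = wx * orientation[0] + wy * orientation[1] + wz * orientation[2]
    with np.errstate(invalid="ignore"):
        directional = np.where(proj > 0, (proj / np.maximum(wmag, 1e-300)) ** 2, 0.0)
    response = radial * directional
    kernel_full = np.fft.fftshift(np.fft.ifftn(response))
    c = n // 2
    h = size // 2
    kernel = kernel_full[c - h:c + h + 1, c - h:c + h + 1, c - h:c + h + 1].copy()
    # remove residual DC introduced by cropping (keeps even/odd symmetry)
    kernel -= kernel.real.mean()
    # zero the first moments of the odd (imaginary) part so linear intensity
    # ramps (shadings) produce no response; cropping reintroduces a small
    # moment that would otherwise leak through the edge detector
    xs = np.arange(size) - h
    coords = np.meshgrid(xs, xs, xs, indexing="ij")
    for axis_coord in coords:
        moment = np.sum(axis_coord * kernel.imag)
        kernel = kernel - 1j * (moment / np.sum(axis_coord ** 2)) * axis_coord
    x, y, z = np.meshgrid(xs, xs, xs, indexing="ij")
    phase = center_frequency * (orientation[0] * x + orientation[1] * y
                                + orientation[2] * z)
    peak = np.abs(np.sum(kernel * np.exp(-1j * phase)))
    return kernel / peak


def build_filter_bank(mode: str = "linear", size: int = 7,
                      center_frequency: float = np.pi / 3.0,
                      bandwidth: float = 2.0) -> QuadratureFilterBank:
    """Build the 3-filter (axis-aligned) or 6-filter (icosahedral) bank.

    ``mode='linear'`` gives filters along x, y, z for the affine algorithm;
    ``mode='morphon'`` gives six filters evenly distributed on the half
    sphere of an icosahedron for the non-linear algorithm.
    """
    if size % 2 == 0 or size < 5:
        raise ParameterError(f"filter size must be odd and >= 5, got {size}")
    if not 0.0 < center_frequency < np.pi:
        raise ParameterError(
            f"center_frequency must be in (0, pi), got {center_frequency}")
    if mode == "linear":
        raw = _AXES_RAW
    elif mode == "morphon":
        raw = _ICOSA_RAW
    else:
        raise ParameterError(f"mode must be 'linear' or 'morphon', got {mode!r}")
    orientations = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    kernels = [_design_kernel(o, size, center_frequency, bandwidth)
               for o in orientations]
    return QuadratureFilterBank(kernels=kernels, orientations=orientations,
                                center_frequency=center_frequency,
                                bandwidth=bandwidth)


def convolve_complex(volume: np.ndarray, kernel: np.ndarray,
                     mode: str = "same") -> np.ndarray:
    """Complex 3D convolution (zero padding in 'same' mode).

    'valid' returns only responses where the kernel lies fully inside the
    volume: shape (X-kx+1, Y-ky+1, Z-kz+1).
    """
    volume = np.asarray(volume)
    kernel = np.asarray(kernel)
    if volume.ndim != 3 or kernel.ndim != 3:
        raise ParameterError("convolve_complex needs 3D volume and kernel")
    if any(k % 2 == 0 for k in kernel.shape):
        raise ParameterError(f"kernel dimensions must be odd, got {kernel.shape}")
    if mode not in ("same", "valid"):
        raise ParameterError(f"mode must be 'same' or 'valid', got {mode!r}")
    if mode == "valid" and any(v < k for v, k in zip(volume.shape, kernel.shape)):
        raise ParameterError(
            f"volume {volume.shape} smaller than kernel {kernel.shape} in valid mode")
    return fftconvolve(volume, kernel, mode=mode)


def apply_bank(volume: np.ndarray, bank: QuadratureFilterBank) -> list[np.ndarray]:
    """Filter responses q_k of every kernel in the bank ('same' mode)."""
    return [convolve_complex(volume, k, mode="same") for k in bank.kernels]


def phase_match(q1: np.ndarray, q2: np.ndarray) -> PhaseMatchField:
    """Phase difference dphi = arg(q1 * conj(q2)) wrapped to (-pi, pi] and
    certainty c = sqrt(|q1||q2|) * cos^2(dphi / 2).

    The certainty vanishes wherever either response magnitude is zero and
    penalizes inconsistent (near-opposite) phases.
    """
    q1 = np.asarray(q1)
    q2 = np.asarray(q2)
    if q1.shape != q2.shape:
        raise ParameterError(f"shape mismatch: {q1.shape} vs {q2.shape}")
    cross = q1 * np.conj(q2)
    delta_phi = np.angle(cross)
    certainty = np.sqrt(np.abs(q1) * np.abs(q2)) * np.cos(delta_phi / 2.0) ** 2
    return PhaseMatchField(delta_phi=delta_phi, certainty=certainty)


def phase_gradient(q: np.ndarray, axis: int | str) -> np.ndarray:
    """Wrap-safe phase derivative along one axis, radians/voxel.

    Interior: arg(q(x+1) * conj(q(x-1))) / 2 (central difference that never
    sees a 2*pi jump); borders use the one-sided arg(q(x+1) * conj(q(x))).
    """
    axis_map = {"x": 0, "y": 1, "z": 2}
    if isinstance(axis, str):
        if axis not in axis_map:
            raise ParameterError(f"axis must be x, y or z, got {axis!r}")
        axis = axis_map[axis]
    if axis not in (0, 1, 2):
        raise ParameterError(f"axis must be 0, 1 or 2, got {axis}")
    q = np.asarray(q)
    if q.shape[axis] < 3:
        raise ParameterError(f"grid extent must be >= 3 along axis {axis}")
    q = np.moveaxis(q, axis, 0)
    grad = np.empty(q.shape, dtype=np.float64)
    grad[1:-1] = np.angle(q[2:] * np.conj(q[:-2])) / 2.0
    grad[0] = np.angle(q[1] * np.conj(q[0]))
    grad[-1] = np.angle(q[-1] * np.conj(q[-2]))
    return np.moveaxis(grad, 0, axis)


def phase_gradient_vector(q: np.ndarray) -> np.ndarray:
    """Stack the three axis gradients into a (..., 3) field."""
    return np.stack([phase_gradient(q, a) for a in range(3)], axis=-1)


def structure_tensor(responses: list[np.ndarray],
                     bank: QuadratureFilterBank) -> TensorField:
    """Local structure tensor T = sum_k |q_k| (5/4 n_k n_k^T - 1/4 I).

    Requires the 6-filter icosahedral bank; the tensor summarizes local
    orientation and anisotropy and weights the Morphon displacement solve.
    """
    if bank.count != 6 or len(responses) != 6:
        raise ParameterError(
            f"structure tensor needs 6 filter responses, got {len(responses)}")
    shape = responses[0].shape
    comps = np.zeros(shape + (6,), dtype=np.float64)
    idx = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    for q, n in zip(responses, bank.orientations):
        mag = np.abs(q)
        outer = np.outer(n, n)
        for c, (i, j) in enumerate(idx):
            term = 1.25 * outer[i, j] - (0.25 if i == j else 0.0)
            comps[..., c] += mag * term
    return TensorField(components=comps)
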