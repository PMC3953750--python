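"""Phase-based affine/rigid registration and motion correction.

The algorithm linearizes the optical-flow constraint over the whole volume:
a 12-parameter affine motion model v(x) = B(x) p is fitted by least squares
to per-voxel phase differences and phase gradients from three axis-aligned
quadrature filters, giving a 12x12 normal-equation system A p = h summed
over all voxels (certainty-weighted). Iterating with parameter accumulation
(the moving volume is always re-interpolated from the original) and a
coarse-to-fine pyramid handles displacements beyond the filter wavelength.
Rigid transforms are obtained by projecting the 3x3 linear part onto the
closest rotation (SVD with singular values forced to one), and rotation
angles are extracted with a four-quadrant arctangent scheme.

Transform convention: p maps reference-space coordinates to moving-space
sample locations (pull-back), with coordinates centered on the volume
midpoint so rotations pivot about the center.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .io import Volume, FmriSeries
from . import quadrature as qd


class IllPosedError(RuntimeError):
    """The registration normal equations cannot be solved reliably."""


@dataclasses.dataclass
class AffineParams:
    """12-vector p: p[0:3] translations (voxels), p[3:12] the row-major 3x3
    *difference* from the identity matrix."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64).reshape(12)
        if not np.all(np.isfinite(self.p)):
            raise ValueError("affine parameters must be finite")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.zeros(12))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, translation: np.ndarray) -> "AffineParams":
        """Build from a full 3x3 matrix (identity included) and translation."""
        p = np.empty(12)
        p[:3] = np.asarray(translation, dtype=np.float64)
        p[3:] = (np.asarray(matrix, dtype=np.float64) - np.eye(3)).ravel()
        return cls(p)

    @property
    def translation(self) -> np.ndarray:
        return self.p[:3]

    @property
    def matrix_with_identity(self) -> np.ndarray:
        return self.p[3:].reshape(3, 3) + np.eye(3)

    def homogeneous(self) -> np.ndarray:
        h = np.eye(4)
        h[:3, :3] = self.matrix_with_identity
        h[:3, 3] = self.translation
        return h

    def compose(self, inner: "AffineParams") -> "AffineParams":
        """self o inner: apply ``inner`` first, then ``self`` (pull-back order:
        sample location = self(inner(x)))."""
        h = self.homogeneous() @ inner.homogeneous()
        return AffineParams.from_matrix(h[:3, :3], h[:3, 3])

    def inverse(self) -> "AffineParams":
        h = np.linalg.inv(self.homogeneous())
        return AffineParams.from_matrix(h[:3, :3], h[:3, 3])


@dataclasses.dataclass
class NormalEquations:
    A: np.ndarray  # 12x12, symmetric
    h: np.ndarray  # 12


@dataclasses.dataclass
class EulerAngles:
    theta1: float
    theta2: float
    theta3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3])


def _centered_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    """Voxel coordinate grids centered on the volume midpoint."""
    axes = [np.arange(n, dtype=np.float64) - (n - 1) / 2.0 for n in shape]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def accumulate_normal_equations(matches: list[qd.PhaseMatchField],
                                gradients: list[np.ndarray],
                                mask: np.ndarray) -> NormalEquations:
    """Certainty-weighted 12x12 normal equations over masked voxels.

    For every filter and voxel, the motion-model basis row B(x) combines the
    phase gradient with the centered voxel coordinates; the contribution is
    w * (B^T grad)(B^T grad)^T to A and w * (B^T grad) * dphi to h with
    w = c^2, the squared phase-match certainty (the same weighting the
    per-voxel non-linear displacement solve uses; squaring suppresses
    voxels with inconsistent phase and measurably reduces the bias of
    recovered rotations).
    """
    if len(matches) != len(gradients):
        raise ValueError("one gradient field per match field required")
    shape = matches[0].delta_phi.shape
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != field shape {shape}")
    x, y, z = _centered_coords(shape)
    xm, ym, zm = x[mask], y[mask], z[mask]

    A = np.zeros((12, 12))
    h = np.zeros(12)
    n_contributing = 0
    for match, grad in zip(matches, gradients):
        if match.delta_phi.shape != shape or grad.shape[:-1] != shape:
            raise ValueError("all fields must share one shape")
        c = match.certainty[mask] ** 2
        good = c > 0
        n_contributing = max(n_contributing, int(good.sum()))
        gx, gy, gz = grad[mask, 0], grad[mask, 1], grad[mask, 2]
        dphi = match.delta_phi[mask]
        # rows of B^T grad for the 12 parameters
        bg = np.stack([
            gx, gy, gz,
            gx * xm, gx * ym, gx * zm,
            gy * xm, gy * ym, gy * zm,
            gz * xm, gz * ym, gz * zm,
        ])  # (12, V)
        wbg = bg * c
        A += wbg @ bg.T
        h += wbg @ dphi
    if n_contributing < 12:
        raise IllPosedError(
            f"only {n_contributing} voxels with positive certainty (need >= 12)")
    A = 0.5 * (A + A.T)
    return NormalEquations(A=A, h=h)


def solve_parameters(eqs: NormalEquations) -> AffineParams:
    """p = A^-1 h, guarded by a condition-number check."""
    cond = np.linalg.cond(eqs.A)
    if not np.isfinite(cond) or cond > 1e12:
        raise IllPosedError(f"normal equations ill-conditioned (cond={cond:.3g})")
    p = np.linalg.solve(eqs.A, eqs.h)
    hnorm = np.linalg.norm(eqs.h)
    if hnorm > 0 and np.linalg.norm(eqs.A @ p - eqs.h) > 1e-6 * hnorm:
        raise IllPosedError("linear solve did not reach requested residual")
    return AffineParams(p)


def apply_affine(volume: Volume | np.ndarray, params: AffineParams,
                 interpolation: str = "trilinear") -> Volume | np.ndarray:
    """Pull-back resampling: output voxel x is looked up at params(x) in the
    source; out-of-volume samples are zero."""
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unsupported interpolation {interpolation!r}")
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    order = 1 if interpolation == "trilinear" else 0
    x, y, z = _centered_coords(data.shape)
    m = params.matrix_with_identity
    t = params.translation
    center = [(n - 1) / 2.0 for n in data.shape]
    sx = center[0] + t[0] + m[0, 0] * x + m[0, 1] * y + m[0, 2] * z
    sy = center[1] + t[1] + m[1, 0] * x + m[1, 1] * y + m[1, 2] * z
    sz = center[2] + t[2] + m[2, 0] * x + m[2, 1] * y + m[2, 2] * z
    out = ndimage.map_coordinates(data, [sx, sy, sz], order=order,
                                  mode="constant", cval=0.0, prefilter=False)
    if isinstance(volume, Volume):
        return volume.like(out)
    return out


def restrict_to_rigid(params: AffineParams) -> AffineParams:
    """Replace the linear part by the closest proper rotation (SVD with all
    singular values forced to one, determinant +1); translations untouched."""
    m = params.matrix_with_identity
    if abs(np.linalg.det(m)) < 1e-12:
        raise IllPosedError("transformation matrix is singular")
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    return AffineParams.from_matrix(r, params.translation.copy())


def extract_euler_angles(params: AffineParams) -> EulerAngles:
    """Rotation angles from the (identity-added) matrix via atan2.

    theta1 = atan2(m12, m22); theta2 = atan2(-m02, sqrt(m00^2 + m01^2));
    theta3 = atan2(s1*m20 - c1*m10, c1*m11 - s1*m21). Near gimbal lock
    (|theta2| -> pi/2) the convention collapses to theta1 = 0 without NaNs.
    """
    m = params.matrix_with_identity
    if np.abs(m @ m.T - np.eye(3)).max() > 1e-6:
        raise ValueError("linear part is not a rotation; restrict_to_rigid first")
    theta1 = np.arctan2(m[1, 2], m[2, 2])
    c2 = np.hypot(m[0, 0], m[0, 1])
    theta2 = np.arctan2(-m[0, 2], c2)
    s1, c1 = np.sin(theta1), np.cos(theta1)
    theta3 = np.arctan2(s1 * m[2, 0] - c1 * m[1, 0],
                        c1 * m[1, 1] - s1 * m[2, 1])
    return EulerAngles(float(theta1), float(theta2), float(theta3))


def compose_euler(theta1: float, theta2: float, theta3: float) -> np.ndarray:
    """Rotation matrix whose extract_euler_angles round-trips (t1, t2, t3)."""
    c1, s1 = np.cos(theta1), np.sin(theta1)
    c2, s2 = np.cos(theta2), np.sin(theta2)
    c3, s3 = np.cos(theta3), np.sin(theta3)
    rx = np.array([[1, 0, 0], [0, c1, -s1], [0, s1, c1]])
    ry = np.array([[c2, 0, s2], [0, 1, 0], [-s2, 0, c2]])
    rz = np.array([[c3, -s3, 0], [s3, c3, 0], [0, 0, 1]])
    return (rz @ ry @ rx).T


def _decimate(data: np.ndarray, fwhm: float = 2.0) -> np.ndarray:
    """Gaussian anti-alias blur (FWHM in voxels) then factor-2 decimation."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    blurred = ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")
    return blurred[::2, ::2, ::2]


def _pyramid(data: np.ndarray, scales: int, min_extent: int) -> list[np.ndarray]:
    """Coarse-to-fine list of decimated volumes; levels whose smallest axis
    would drop below ``min_extent`` are skipped."""
    levels = [data]
    for _ in range(scales - 1):
        nxt = _decimate(levels[-1])
        if min(nxt.shape) < min_extent:
            break
        levels.append(nxt)
    return levels[::-1]


def _interior_mask(shape: tuple[int, int, int], border: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(border, n - border) for n in shape)
    if all(s.stop > s.start for s in sl):
        mask[sl] = True
    return mask


def estimate_transform(reference: Volume | np.ndarray, moving: Volume | np.ndarray,
                       model: str = "affine", scales: int = 3,
                       iterations_per_scale: int = 10,
                       bank: qd.QuadratureFilterBank | None = None,
                       ) -> tuple[AffineParams, np.ndarray]:
    """Multiscale phase-based estimation of the transform aligning ``moving``
    to ``reference``; returns the accumulated parameters and the registered
    moving volume.

    Parameters are accumulated across iterations (the moving volume is
    re-interpolated once per iteration from the original at the current
    pyramid level, never repeatedly). With ``model='rigid'`` the linear part
    is projected onto a rotation after every iteration. If one scale's solve
    is ill-posed, the incoming parameters are kept with a warning.
    """
    if model not in ("affine", "rigid"):
        raise ValueError(f"model must be 'affine' or 'rigid', got {model!r}")
    if scales < 1:
        raise ValueError("scales must be >= 1")
    ref = reference.data if isinstance(reference, Volume) else np.asarray(reference, float)
    mov = moving.data if isinstance(moving, Volume) else np.asarray(moving, float)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {mov.shape}")
    if ref.std() < 1e-12 or mov.std() < 1e-12:
        raise IllPosedError("constant-intensity volume cannot be registered")
    if bank is None:
        bank = qd.build_filter_bank("linear")
    border = bank.size // 2

    ref_levels = _pyramid(ref, scales, min_extent=2 * bank.size)
    mov_levels = _pyramid(mov, scales, min_extent=2 * bank.size)

    params = AffineParams.identity()
    first = True
    for ref_l, mov_l in zip(ref_levels, mov_levels):
        if not first:
            p = params.p.copy()
            p[:3] *= 2.0  # translations scale with the grid; matrix part does not
            params = AffineParams(p)
        first = False
        ref_resp = qd.apply_bank(ref_l, bank)
        ref_grads = [qd.phase_gradient_vector(q) for q in ref_resp]
        mask = _interior_mask(ref_l.shape, border)
        for _ in range(iterations_per_scale):
            warped = apply_affine(mov_l, params)
            mov_resp = qd.apply_bank(warped, bank)
            matches = [qd.phase_match(qr, qm) for qr, qm in zip(ref_resp, mov_resp)]
            try:
                eqs = accumulate_normal_equations(matches, ref_grads, mask)
                inc = solve_parameters(eqs)
            except IllPosedError as exc:
                warnings.warn(f"scale skipped: {exc}", RuntimeWarning, stacklevel=2)
                break
            params = params.compose(inc)
            if model == "rigid":
                params = restrict_to_rigid(params)
    registered = apply_affine(mov, params)
    if isinstance(moving, Volume):
        registered_out: np.ndarray | Volume = moving.like(registered)
    else:
        registered_out = registered
    return params, registered_out


def motion_correct(series: FmriSeries, reference_index: int = 0,
                   iterations: int = 3, scales: int = 2,
                   ) -> tuple[FmriSeries, np.ndarray]:
    """Rigid registration of every volume to the reference volume.

    Returns the corrected series and a T x 6 motion trace (3 translations in
    voxels, 3 rotation angles in degrees); the reference row is all zeros.
    Volumes whose registration is ill-posed get an identity transform and a
    warning.
    """
    if series.n_volumes < 2:
        raise ValueError("motion correction needs at least 2 volumes")
    if not 0 <= reference_index < series.n_volumes:
        raise ValueError(f"reference_index {reference_index} out of range")
    bank = qd.build_filter_bank("linear")
    ref = series.data[..., reference_index]
    corrected = np.empty_like(series.data)
    trace = np.zeros((series.n_volumes, 6))
    for t in range(series.n_volumes):
        if t == reference_index:
            corrected[..., t] = series.data[..., t]
            continue
        try:
            params, registered = estimate_transform(
                ref, series.data[..., t], model="rigid", scales=scales,
                iterations_per_scale=iterations, bank=bank)
        except IllPosedError as exc:
            warnings.warn(f"volume {t}: {exc}; identity recorded",
                          RuntimeWarning, stacklevel=2)
            corrected[..., t] = series.data[..., t]
            continue
        corrected[..., t] = registered
        angles = extract_euler_angles(params)
        trace[t, :3] = params.translation
        trace[t, 3:] = np.degrees(angles.as_array())
    out = FmriSeries(corrected, repetition_time=series.repetition_time,
                     voxel_size=series.voxel_size, affine=series.affine.copy())
    return out, trace
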