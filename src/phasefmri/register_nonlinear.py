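"""Morphon non-linear registration.

The Morphon drives a dense displacement field from the same local-phase
machinery as the affine algorithm, but solves one small system per voxel
instead of one global system: six icosahedrally oriented quadrature filters
yield per-filter phase differences dphi_k and certainties c_k, and a local
structure tensor T reinforces displacement estimates along the dominant
local orientation (perpendicular to edges and lines). The per-voxel
least-squares solution is

    d = (sum_k c_k^2 T^T T)^(-1) sum_k c_k^2 dphi_k T^T T n_k

followed by Gaussian regularization of each displacement component. The
field is accumulated across iterations by composition (the moving volume is
always warped from the original), and an affine pre-alignment seeds the
estimation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import Volume
from . import quadrature as qd
from . import register_linear as rl


@dataclasses.dataclass
class DisplacementField:
    """Per-voxel displacement (dx, dy, dz) in voxels, shape (X, Y, Z, 3)."""

    components: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float64)
        if self.components.ndim != 4 or self.components.shape[-1] != 3:
            raise ValueError(
                f"displacement field must be (X, Y, Z, 3), got {self.components.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    @classmethod
    def zeros(cls, shape) -> "DisplacementField":
        return cls(np.zeros(tuple(shape) + (3,)))

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.sum(self.components ** 2, axis=-1))))


def solve_displacement(tensor: qd.TensorField,
                       matches: list[qd.PhaseMatchField],
                       bank: qd.QuadratureFilterBank) -> DisplacementField:
    """Per-voxel tensor-weighted displacement solve.

    Voxels whose 3x3 system has condition number above 1e8 (or zero
    certainty everywhere) get zero displacement — rank-deficient tensors
    simply do not constrain the orthogonal directions.
    """
    if bank.count != 6 or len(matches) != 6:
        raise ValueError("Morphon solve needs 6 match fields and a 6-filter bank")
    shape = tensor.components.shape[:-1]
    for m in matches:
        if m.delta_phi.shape != shape:
            raise ValueError("match fields must align with the tensor grid")
    t_mat = tensor.as_matrices().reshape(-1, 3, 3)
    t2 = np.einsum("vij,vjk->vik", t_mat, t_mat)

    csum = np.zeros(t_mat.shape[0])
    v = np.zeros((t_mat.shape[0], 3))
    for match, n in zip(matches, bank.orientations):
        c2 = (match.certainty ** 2).reshape(-1)
        csum += c2
        v += (c2 * match.delta_phi.reshape(-1))[:, None] * n[None, :]
    A = csum[:, None, None] * t2
    b = np.einsum("vij,vj->vi", t2, v)

    eig = np.linalg.eigvalsh(A)
    lo, hi = eig[:, 0], eig[:, -1]
    good = (csum > 0) & (lo > 0) & (hi < 1e8 * lo)
    d = np.zeros((t_mat.shape[0], 3))
    if good.any():
        d[good] = np.linalg.solve(A[good], b[good][..., None])[..., 0]
    return DisplacementField(d.reshape(shape + (3,)))


def regularize_field(field: DisplacementField, fwhm: float) -> DisplacementField:
    """Gaussian smoothing applied separately to each motion component;
    fwhm (voxels) = 0 is the identity."""
    if fwhm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm}")
    if fwhm == 0:
        return DisplacementField(field.components.copy())
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = np.empty_like(field.components)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(field.components[..., c],
                                              sigma=sigma, mode="constant")
    return DisplacementField(out)


def warp_volume(volume: Volume | np.ndarray, field: DisplacementField,
                interpolation: str = "trilinear") -> Volume | np.ndarray:
    """Pull-back warp: output voxel x is looked up at x + d(x); samples
    outside the volume are zero."""
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, float)
    if data.shape != field.shape:
        raise ValueError(f"volume {data.shape} vs field {field.shape}")
    order = 1 if interpolation == "trilinear" else 0
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in data.shape],
                        indexing="ij")
    coords = [g + field.components[..., i] for i, g in enumerate(grids)]
    out = ndimage.map_coordinates(data, coords, order=order, mode="constant",
                                  cval=0.0, prefilter=False)
    if isinstance(volume, Volume):
        return volume.like(out)
    return out


def compose_fields(old: DisplacementField, inc: DisplacementField,
                   ) -> DisplacementField:
    """Accumulate: total(x) = inc(x) + old(x + inc(x)) (trilinear lookup),
    so warping by the total equals warping by ``old`` after ``inc``."""
    if old.shape != inc.shape:
        raise ValueError("field shapes differ")
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in old.shape],
                        indexing="ij")
    coords = [g + inc.components[..., i] for i, g in enumerate(grids)]
    total = inc.components.copy()
    for c in range(3):
        total[..., c] += ndimage.map_coordinates(
            old.components[..., c], coords, order=1, mode="nearest", prefilter=False)
    return DisplacementField(total)


def _upsample_field(field: DisplacementField, target_shape) -> DisplacementField:
    """Move a field to a finer grid: resample and double the displacements."""
    out = np.empty(tuple(target_shape) + (3,))
    factors = [t / s for t, s in zip(target_shape, field.shape)]
    for c in range(3):
        out[..., c] = ndimage.zoom(field.components[..., c], factors, order=1,
                                   mode="nearest", grid_mode=True) * 2.0
    return DisplacementField(out)


def affine_to_field(params: rl.AffineParams, shape) -> DisplacementField:
    """Displacement-field view of an affine transform on a given grid."""
    x, y, z = rl._centered_coords(shape)
    m = params.matrix_with_identity
    t = params.translation
    dx = t[0] + (m[0, 0] - 1) * x + m[0, 1] * y + m[0, 2] * z
    dy = t[1] + m[1, 0] * x + (m[1, 1] - 1) * y + m[1, 2] * z
    dz = t[2] + m[2, 0] * x + m[2, 1] * y + (m[2, 2] - 1) * z
    return DisplacementField(np.stack([dx, dy, dz], axis=-1))


def morphon_register(reference: Volume | np.ndarray, moving: Volume | np.ndarray,
                     scales: int = 2, iterations_per_scale: int = 5,
                     regularization_fwhm: float = 4.0,
                     affine_prestep: bool = True,
                     ) -> tuple[DisplacementField, np.ndarray | Volume]:
    """Full Morphon pipeline: affine pre-alignment, then per scale
    filter -> phase match -> structure tensor -> per-voxel solve ->
    regularize -> accumulate -> warp. The returned field has the affine part
    composed in; the warped volume is interpolated once from the original.

    The regularization FWHM (voxels) applies per scale and is halved at the
    finest scale.
    """
    ref = reference.data if isinstance(reference, Volume) else np.asarray(reference, float)
    mov = moving.data if isinstance(moving, Volume) else np.asarray(moving, float)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {mov.shape}")
    bank = qd.build_filter_bank("morphon")

    if affine_prestep:
        affine_params, mov_aff = rl.estimate_transform(
            ref, mov, model="affine", scales=scales, iterations_per_scale=5)
        mov_aff = np.asarray(mov_aff.data if isinstance(mov_aff, Volume) else mov_aff)
    else:
        affine_params = rl.AffineParams.identity()
        mov_aff = mov

    ref_levels = rl._pyramid(ref, scales, min_extent=2 * bank.size)
    mov_levels = rl._pyramid(mov_aff, scales, min_extent=2 * bank.size)

    field = DisplacementField.zeros(ref_levels[0].shape)
    for li, (ref_l, mov_l) in enumerate(zip(ref_levels, mov_levels)):
        if li > 0:
            field = _upsample_field(field, ref_l.shape)
        finest = li == len(ref_levels) - 1
        fwhm = regularization_fwhm / 2.0 if finest else regularization_fwhm
        ref_resp = qd.apply_bank(ref_l, bank)
        tensor = qd.structure_tensor(ref_resp, bank)
        for _ in range(iterations_per_scale):
            warped = warp_volume(mov_l, field)
            mov_resp = qd.apply_bank(warped, bank)
            matches = [qd.phase_match(qr, qm)
                       for qr, qm in zip(ref_resp, mov_resp)]
            inc = solve_displacement(tensor, matches, bank)
            # responses in the border halo are corrupted by zero padding
            halo = ~rl._interior_mask(ref_l.shape, bank.size // 2)
            inc.components[halo] = 0.0
            inc = regularize_field(inc, fwhm)
            field = compose_fields(field, inc)

    # compose the affine pre-step in: d_total(x) = f(x) + v_aff(x + f(x))
    if affine_prestep:
        aff_field = affine_to_field(affine_params, ref.shape)
        total = compose_fields(aff_field, field)
    else:
        total = field
    warped_final = warp_volume(mov, total)
    if isinstance(moving, Volume):
        warped_out: Volume | np.ndarray = moving.like(warped_final)
    else:
        warped_out = warped_final
    return total, warped_out
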