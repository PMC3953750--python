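"""NIfTI-1 and plain-text IO: the ``Volume`` / ``FmriSeries`` containers,
design/contrast/motion/null-distribution parsers, and their writers.

All on-disk images are NIfTI-1 (via nibabel); data is stored float32 on disk
and promoted to float64 in memory for accumulation-heavy computations.
Voxel indices are 0-based; world coordinates follow the NIfTI affine.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import nibabel as nib


class FormatError(ValueError):
    """Raised for malformed image or text inputs."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with voxel size (mm) and a voxel-to-world affine."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"Volume needs 3D data, got shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise FormatError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray) -> "Volume":
        """New volume with this volume's spatial metadata."""
        return Volume(data, voxel_size=self.voxel_size, affine=self.affine.copy())


@dataclasses.dataclass
class FmriSeries:
    """A 4D grid (x, y, z, t) with repetition time in seconds."""

    data: np.ndarray
    repetition_time: float = 2.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise FormatError(f"FmriSeries needs 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise FormatError("FmriSeries needs at least one time point")
        if self.repetition_time <= 0:
            raise FormatError(f"repetition_time must be > 0, got {self.repetition_time}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def volume(self, index: int) -> Volume:
        """Extract one 3D volume with inherited spatial metadata."""
        return Volume(self.data[..., index], voxel_size=self.voxel_size,
                      affine=self.affine.copy())


def read_nifti(path: str | os.PathLike) -> Volume | FmriSeries:
    """Read a .nii/.nii.gz file; dimensionality decides the return type.

    scl_slope/scl_inter scaling is applied (nibabel get_fdata). A 4D file
    returns an :class:`FmriSeries` with TR taken from pixdim[4].
    """
    try:
        img = nib.load(str(path))
        data = img.get_fdata(dtype=np.float64)
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises various header errors
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if data.ndim == 3:
        return Volume(data, voxel_size=voxel_size, affine=img.affine)
    if data.ndim == 4:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return FmriSeries(data, repetition_time=tr, voxel_size=voxel_size,
                          affine=img.affine)
    raise FormatError(f"unsupported NIfTI dimensionality {data.ndim} in {path}")


def write_nifti(obj: Volume | FmriSeries, path: str | os.PathLike,
                description: str = "") -> None:
    """Write float32 NIfTI-1; ``description`` lands in the header descrip field."""
    img = nib.Nifti1Image(np.asarray(obj.data, dtype=np.float32), obj.affine)
    zooms = list(obj.voxel_size)
    if isinstance(obj, FmriSeries):
        zooms.append(obj.repetition_time)
    img.header.set_zooms(tuple(zooms))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def _read_numeric_table(path: str | os.PathLike, comment_chars=("#", "/")) -> np.ndarray:
    """Whitespace-delimited numeric text; comment lines start with '#' or '/'."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(comment_chars):
                continue
            try:
                row = [float(tok) for tok in stripped.split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric token") from exc
            if rows and len(row) != len(rows[0]):
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(row)} values, "
                    f"expected {len(rows[0])})")
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no numeric rows")
    return np.asarray(rows, dtype=np.float64)


def read_design(path: str | os.PathLike) -> np.ndarray:
    """Task regressors as a T x K array (FSL .mat header lines skipped)."""
    return _read_numeric_table(path)


def read_contrast(path: str | os.PathLike) -> np.ndarray:
    """Contrast rows as an N x R array (FSL .con header lines skipped)."""
    return _read_numeric_table(path)


def read_motion_par(path: str | os.PathLike) -> np.ndarray:
    """Motion trace T x 6: translations then rotations (degrees)."""
    table = _read_numeric_table(path)
    if table.shape[1] != 6:
        raise FormatError(f"{path}: motion .par needs 6 columns, got {table.shape[1]}")
    return table


def write_motion_par(path: str | os.PathLike, trace: np.ndarray) -> None:
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise FormatError(f"motion trace must be T x 6, got {trace.shape}")
    np.savetxt(str(path), trace, fmt="%.8f")


def write_null(path: str | os.PathLike, values: np.ndarray) -> None:
    """Null distribution, one maximum statistic per line, sorted ascending."""
    np.savetxt(str(path), np.sort(np.asarray(values, dtype=np.float64)), fmt="%.10g")


def read_null(path: str | os.PathLike) -> np.ndarray:
    table = _read_numeric_table(path)
    return np.sort(table.ravel())
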