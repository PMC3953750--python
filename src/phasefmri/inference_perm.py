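"""Non-parametric maximum-statistic permutation inference.

In every permutation only the largest value of the statistic map (the
maximum t/F, or the extent or mass of the largest suprathreshold cluster)
is kept, forming the null distribution of the image-wide maximum; corrected
p-values are the proportion of null values larger than or equal to the
observed value, which controls familywise error across voxels. Second-level
permutations relabel subjects (sign flips for one-sample designs, design-row
permutation otherwise). First-level permutations whiten the detrended data
once with a voxel-wise AR(4) model, permute the whitened residual series in
time (the same permutation at every voxel, preserving spatial structure),
re-impose the autocorrelation by running the AR recursion forward, and
re-apply smoothing and OLS in every permutation — the analysis in each
permutation is identical to the observed one, which is what makes the
p-values valid.

The identity permutation is always forced into the permutation set, so the
smallest achievable corrected p is 1/n_permutations.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from itertools import permutations as iter_permutations, product as iter_product

import numpy as np
from scipy import ndimage as _ndimage  # smoothing only; labeling is hand-written

from .io import FmriSeries
from . import glm as glm_mod
from .preprocess import FWHM_TO_SIGMA


@dataclasses.dataclass
class NullDistribution:
    """Sorted per-permutation maximum statistics."""

    values: np.ndarray
    kind: str = "voxel_max"  # voxel_max | cluster_extent | cluster_mass
    cdt: float | None = None

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=np.float64))
        if self.values.size == 0:
            raise ValueError("null distribution is empty")

    @property
    def n_permutations(self) -> int:
        return int(self.values.size)


@dataclasses.dataclass
class ClusterLabeling:
    """Connected components of the suprathreshold set (0 = background)."""

    labels: np.ndarray
    sizes: np.ndarray    # voxel count per cluster, index label-1
    masses: np.ndarray   # summed statistic per cluster

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)


def label_clusters(stat_map: np.ndarray, threshold: float,
                   connectivity: int = 26) -> ClusterLabeling:
    """26-connectivity connected components of {stat > threshold}.

    Union-find with path compression over the suprathreshold voxels;
    components are numbered deterministically by their smallest linear
    voxel index.
    """
    if connectivity != 26:
        raise ValueError("only 26-connectivity is supported")
    stat = np.asarray(stat_map, dtype=np.float64)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map contains non-finite values")
    supra = stat > threshold
    labels = np.zeros(stat.shape, dtype=np.int32)
    coords = np.argwhere(supra)
    if coords.size == 0:
        return ClusterLabeling(labels, np.zeros(0, dtype=int), np.zeros(0))
    shape = stat.shape
    lin = np.ravel_multi_index(coords.T, shape)
    id_of = {int(l): i for i, l in enumerate(lin)}
    parent = list(range(len(lin)))

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    # forward half of the 26-neighbourhood avoids double unions
    offsets = [(dx, dy, dz)
               for dx, dy, dz in iter_product((-1, 0, 1), repeat=3)
               if (dx, dy, dz) > (0, 0, 0)]
    for i, (x, y, z) in enumerate(coords):
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2] \
                    and supra[nx, ny, nz]:
                j = id_of[int(np.ravel_multi_index((nx, ny, nz), shape))]
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    roots = np.fromiter((find(i) for i in range(len(lin))), dtype=np.int64)
    unique_roots, inverse = np.unique(roots, return_inverse=True)
    # roots are ordered by first appearance in lin order = smallest index
    labels[tuple(coords.T)] = inverse + 1
    sizes = np.bincount(inverse, minlength=unique_roots.size)
    masses = np.bincount(inverse, weights=stat[tuple(coords.T)],
                         minlength=unique_roots.size)
    return ClusterLabeling(labels, sizes, masses)


def corrected_pvalues(observed: np.ndarray, null: NullDistribution) -> np.ndarray:
    """p = #{null >= observed} / n_permutations (the printed convention,
    without a +1 correction; the identity permutation being part of the
    null keeps p positive for the observed maximum)."""
    obs = np.asarray(observed, dtype=np.float64)
    n = null.n_permutations
    counts = n - np.searchsorted(null.values, obs, side="left")
    return counts / n


def significance_threshold(null: NullDistribution, alpha_percent: float) -> float:
    """The null value larger than (100 - alpha)% of the sorted values.

    With ties the returned value is the order statistic at the ceiling rank,
    which may equal lower entries; applying the threshold with strict '>'
    keeps the empirical FWE at or below alpha (up to the 1/n granularity).
    """
    if not 0 < alpha_percent < 100:
        raise ValueError(f"alpha must be in (0, 100), got {alpha_percent}")
    n = null.n_permutations
    k = math.ceil((100.0 - alpha_percent) / 100.0 * n)
    return float(null.values[min(k, n - 1)])


def _max_cluster_stat(stat: np.ndarray, cdt: float, kind: str) -> float:
    labeling = label_clusters(stat, cdt)
    if labeling.n_clusters == 0:
        return 0.0
    return float(labeling.sizes.max() if kind == "cluster_extent"
                 else labeling.masses.max())


@dataclasses.dataclass
class PermutationResult:
    null: NullDistribution
    p_map: np.ndarray          # corrected p per voxel (cluster p for members)
    stat_map: np.ndarray
    clusters: ClusterLabeling | None = None
    cluster_p: np.ndarray | None = None


def _second_level_relabelings(n_subjects: int, n_permutations: int,
                              scheme: str, rng: np.random.Generator):
    """Yield sign vectors or row orders; identity first; full enumeration
    when the requested count reaches the number of distinct relabelings."""
    if scheme == "sign_flip":
        total = 2 ** n_subjects
        if n_permutations >= total:
            if n_permutations > total:
                warnings.warn(
                    f"{n_permutations} permutations exceed the {total} distinct "
                    "sign patterns; falling back to full enumeration",
                    RuntimeWarning, stacklevel=3)
            signs = [np.array(bits, dtype=float) * 2 - 1
                     for bits in iter_product((1, 0), repeat=n_subjects)]
            return signs[:1] + signs[1:]  # identity (all +1) is first
        out = [np.ones(n_subjects)]
        for _ in range(n_permutations - 1):
            out.append(rng.choice([-1.0, 1.0], size=n_subjects))
        return out
    if scheme == "row_permute":
        total = math.factorial(n_subjects)
        if n_permutations >= total:
            if n_permutations > total:
                warnings.warn(
                    f"{n_permutations} permutations exceed the {total} distinct "
                    "row orders; falling back to full enumeration",
                    RuntimeWarning, stacklevel=3)
            return [np.array(p) for p in iter_permutations(range(n_subjects))]
        out = [np.arange(n_subjects)]
        for _ in range(n_permutations - 1):
            out.append(rng.permutation(n_subjects))
        return out
    raise ValueError(f"scheme must be 'sign_flip' or 'row_permute', got {scheme!r}")


def permutation_test_group(data: np.ndarray, design: glm_mod.DesignMatrix,
                           n_permutations: int = 1000,
                           inference: str = "voxel",
                           cdt: float | None = None,
                           scheme: str | None = None,
                           seed: int = 0,
                           statistic: str = "t") -> PermutationResult:
    """Second-level max-statistic permutation test.

    data: per-subject stat/beta images, shape (S, ...) — any spatial shape.
    No whitening or smoothing is needed at the group level; each permutation
    relabels subjects, refits the GLM and records the maximum statistic (or
    the largest cluster extent/mass above ``cdt``).
    """
    data = np.asarray(data, dtype=np.float64)
    S = data.shape[0]
    if S < 2:
        raise ValueError("need at least 2 subjects")
    spatial_shape = data.shape[1:]
    y = data.reshape(S, -1).T  # (V, S)
    X = design.X
    if X.shape[0] != S:
        raise ValueError(f"design has {X.shape[0]} rows for {S} subjects")
    if inference in ("cluster_extent", "cluster_mass") and cdt is None:
        raise ValueError("cluster inference requires a cluster-defining threshold")
    if scheme is None:
        one_sample = X.shape[1] == 1 and np.allclose(X[:, 0], X[0, 0])
        scheme = "sign_flip" if one_sample else "row_permute"

    rng = np.random.Generator(np.random.Philox(seed))
    relabelings = _second_level_relabelings(S, n_permutations, scheme, rng)

    def stat_for(y_perm: np.ndarray, X_perm: np.ndarray) -> np.ndarray:
        d = dataclasses.replace(design, X=X_perm)
        fit = glm_mod.ols_fit(d, y_perm)
        return glm_mod.contrast_statistic(fit, kind=statistic)

    maxima = np.empty(len(relabelings))
    observed_stat = None
    for i, lab in enumerate(relabelings):
        if scheme == "sign_flip":
            y_perm, X_perm = y * lab[None, :], X
        else:
            y_perm, X_perm = y, X[lab]
        stat = stat_for(y_perm, X_perm)
        stat_vol = stat.reshape(spatial_shape)
        if i == 0:
            observed_stat = stat_vol
        if inference == "voxel":
            maxima[i] = stat.max()
        else:
            kind = inference
            maxima[i] = _max_cluster_stat(stat_vol, cdt, kind)

    null = NullDistribution(maxima, kind="voxel_max" if inference == "voxel"
                            else inference, cdt=cdt)
    if inference == "voxel":
        p_map = corrected_pvalues(observed_stat, null)
        return PermutationResult(null, p_map, observed_stat)
    labeling = label_clusters(observed_stat, cdt)
    cluster_stat = (labeling.sizes if inference == "cluster_extent"
                    else labeling.masses)
    cluster_p = corrected_pvalues(cluster_stat, null) if labeling.n_clusters \
        else np.zeros(0)
    p_map = np.ones(spatial_shape)
    for k in range(labeling.n_clusters):
        p_map[labeling.labels == k + 1] = cluster_p[k]
    return PermutationResult(null, p_map, observed_stat, labeling, cluster_p)


def surrogate_first_level(whitened: np.ndarray, rho: np.ndarray,
                          permutation: np.ndarray) -> np.ndarray:
    """Generate surrogate data: permute the whitened series in time (the
    same permutation at every voxel) and run the AR recursion forward to put
    the autocorrelation back."""
    whitened = np.asarray(whitened, dtype=np.float64)
    T = whitened.shape[-1]
    perm = np.asarray(permutation)
    if sorted(perm.tolist()) != list(range(T)):
        raise ValueError("permutation must be a bijection of 0..T-1")
    permuted = whitened[..., perm]
    return glm_mod.unwhiten_series(permuted, rho)


def _smooth_4d(data: np.ndarray, fwhm_mm: float, voxel_size,
               mask: np.ndarray | None) -> np.ndarray:
    if fwhm_mm <= 0:
        return data
    sigma = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size] + [0.0]
    if mask is None:
        return _ndimage.gaussian_filter(data, sigma=sigma, mode="constant",
                                        truncate=4.0)
    cert = mask.astype(float)
    num = _ndimage.gaussian_filter(data * cert[..., None], sigma=sigma,
                                   mode="constant", truncate=4.0)
    den = _ndimage.gaussian_filter(cert, sigma=sigma[:3], mode="constant",
                                   truncate=4.0)
    den = np.where(den < 1e-6, np.inf, den)
    return num / den[..., None]


def permutation_test_first_level(series: FmriSeries,
                                 design: glm_mod.DesignMatrix,
                                 n_permutations: int = 1000,
                                 smoothing_fwhm_mm: float = 6.0,
                                 inference: str = "voxel",
                                 cdt: float | None = None,
                                 seed: int = 0,
                                 mask: np.ndarray | None = None,
                                 ar_order: int = 4,
                                 ar_smooth_fwhm_mm: float = 7.0,
                                 statistic: str = "t") -> PermutationResult:
    """First-level max-statistic permutation test on motion-corrected data.

    Detrending and AR(4) whitening are applied once; each permutation
    shuffles the whitened data in time, re-imposes the autocorrelation,
    smooths (smoothing alters the autocorrelation, so it must be redone in
    every permutation) and fits OLS. The observed statistic comes from the
    identity permutation processed identically.
    """
    y, mask_b = glm_mod._masked_data(series, mask)
    spatial_shape = mask_b.shape
    T = series.n_volumes
    X = design.X
    if X.shape[0] != T:
        raise ValueError("design rows must equal time points")
    if inference != "voxel" and cdt is None:
        raise ValueError("cluster inference requires a cluster-defining threshold")

    # detrend: project out the trend block once
    D = glm_mod.detrend_block(T)
    beta_d = y @ np.linalg.pinv(D).T
    detrended = y - beta_d @ D.T

    fit0 = glm_mod.ols_fit(design, y)
    rho = glm_mod.estimate_ar_spatial(fit0.residuals, X, mask_b,
                                      voxel_size=series.voxel_size,
                                      order=ar_order,
                                      fwhm_mm=ar_smooth_fwhm_mm)
    whitened = glm_mod.whiten_series(detrended, rho)

    rng = np.random.Generator(np.random.Philox(seed))
    perms = [np.arange(T)] + [rng.permutation(T)
                              for _ in range(n_permutations - 1)]

    maxima = np.empty(len(perms))
    observed_stat = None
    for i, perm in enumerate(perms):
        surrogate = surrogate_first_level(whitened, rho, perm)
        vol4d = np.zeros(spatial_shape + (T,))
        vol4d[mask_b] = surrogate
        smoothed = _smooth_4d(vol4d, smoothing_fwhm_mm, series.voxel_size,
                              mask_b if mask is not None else None)
        fit = glm_mod.ols_fit(design, smoothed[mask_b])
        stat = glm_mod.contrast_statistic(fit, kind=statistic)
        stat_vol = np.zeros(spatial_shape)
        stat_vol[mask_b] = stat
        if i == 0:
            observed_stat = stat_vol
        if inference == "voxel":
            maxima[i] = stat.max()
        else:
            maxima[i] = _max_cluster_stat(stat_vol, cdt, inference)

    null = NullDistribution(maxima, kind="voxel_max" if inference == "voxel"
                            else inference, cdt=cdt)
    if inference == "voxel":
        p_map = corrected_pvalues(observed_stat, null)
        p_map[~mask_b] = 1.0
        return PermutationResult(null, p_map, observed_stat)
    labeling = label_clusters(observed_stat, cdt)
    cluster_stat = (labeling.sizes if inference == "cluster_extent"
                    else labeling.masses)
    cluster_p = corrected_pvalues(cluster_stat, null) if labeling.n_clusters \
        else np.zeros(0)
    p_map = np.ones(spatial_shape)
    for k in range(labeling.n_clusters):
        p_map[labeling.labels == k + 1] = cluster_p[k]
    return PermutationResult(null, p_map, observed_stat, labeling, cluster_p)
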