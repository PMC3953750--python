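"""Voxel-wise general linear model with AR(4) prewhitening.

The model is y = X beta + eps per voxel. Ordinary least squares gives
beta_hat = (X^T X)^(-1) X^T y; t- and F-statistics follow from a contrast
vector c (or matrix C) and the unbiased residual variance
var(eps) = ||eps||^2 / (T - R). First-level errors are modelled as an
autoregressive process eps_t = sum_i rho_i eps_{t-i} + w_t of order 4,
estimated per voxel from the Yule-Walker equations. The Cochrane-Orcutt
procedure alternates OLS, AR estimation (with spatial smoothing of the AR
coefficient maps), and whitening of both the data and every design column,
so each voxel ends up with its own whitened design matrix; statistics are
computed from the whitened residual variance and the voxel-specific
(X~^T X~)^(-1).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import solve_toeplitz

from .io import Volume, FmriSeries
from .preprocess import smooth_normalized

MAX_REGRESSORS = 25


@dataclasses.dataclass
class DesignMatrix:
    """T x R design with columns ordered [task | motion | detrend].

    The detrend block always holds mean, linear, quadratic and cubic trends
    built on normalized time t in [-1, 1]; its columns act like a high-pass
    filter. At most 25 regressors are supported.
    """

    X: np.ndarray
    n_task: int
    n_motion: int
    contrast: np.ndarray | None = None   # (R,) vector or (N, R) matrix
    null_value: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if self.X.shape[1] > MAX_REGRESSORS:
            raise ValueError(
                f"{self.X.shape[1]} regressors exceeds the maximum of "
                f"{MAX_REGRESSORS}")
        if self.contrast is not None:
            self.contrast = np.atleast_2d(np.asarray(self.contrast, float))
            if self.contrast.shape[1] != self.X.shape[1]:
                raise ValueError(
                    f"contrast has {self.contrast.shape[1]} entries for "
                    f"{self.X.shape[1]} regressors")

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]


@dataclasses.dataclass
class GlmFit:
    """Per-voxel fit: beta (V, R), residuals (V, T), sigma2 (V,), optional
    AR coefficients rho (V, p), and the voxel-specific whitened design
    normal matrices when the fit was prewhitened."""

    beta: np.ndarray
    residuals: np.ndarray
    sigma2: np.ndarray
    design: DesignMatrix
    mask: np.ndarray
    dof: int
    rho: np.ndarray | None = None
    xtx_inv: np.ndarray | None = None  # (R, R) shared, or (V, R, R) voxel-wise

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values back into the volume grid."""
        out = np.full(self.mask.shape + values.shape[1:], fill, dtype=float)
        out[self.mask] = values
        return out


def detrend_block(T: int) -> np.ndarray:
    """Mean, linear, quadratic, cubic trend columns on t in [-1, 1]."""
    t = np.linspace(-1.0, 1.0, T)
    return np.stack([np.ones(T), t, t ** 2, t ** 3], axis=1)


def build_design(task_regressors: np.ndarray | None = None,
                 motion: np.ndarray | None = None,
                 n_timepoints: int | None = None,
                 contrast: np.ndarray | None = None,
                 null_value: float | np.ndarray = 0.0) -> DesignMatrix:
    """Assemble [task | motion(6) | mean, linear, quad, cubic].

    ``contrast`` applies to the task block only if its length equals the
    task count (it is zero-padded across motion and detrend columns).
    """
    blocks = []
    n_task = 0
    if task_regressors is not None:
        task = np.atleast_2d(np.asarray(task_regressors, float))
        if n_timepoints is not None and task.shape[0] != n_timepoints:
            task = task.T
        n_task = task.shape[1]
        blocks.append(task)
        n_timepoints = task.shape[0]
    if n_timepoints is None:
        raise ValueError("n_timepoints required without task regressors")
    n_motion = 0
    if motion is not None:
        motion = np.asarray(motion, dtype=np.float64)
        if motion.shape[0] != n_timepoints:
            raise ValueError(
                f"motion trace has {motion.shape[0]} rows for {n_timepoints} "
                "time points")
        n_motion = motion.shape[1]
        blocks.append(motion)
    blocks.append(detrend_block(n_timepoints))
    X = np.hstack(blocks)
    if contrast is not None:
        contrast = np.atleast_2d(np.asarray(contrast, float))
        if contrast.shape[1] == n_task and n_task < X.shape[1]:
            contrast = np.hstack([
                contrast, np.zeros((contrast.shape[0], X.shape[1] - n_task))])
    return DesignMatrix(X, n_task=n_task, n_motion=n_motion,
                        contrast=contrast, null_value=null_value)


def _masked_data(data: FmriSeries | np.ndarray, mask: np.ndarray | None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(V, T) data array plus the boolean mask used."""
    arr = data.data if isinstance(data, FmriSeries) else np.asarray(data, float)
    if mask is None:
        mask = np.ones(arr.shape[:-1], dtype=bool)
    else:
        mask = np.asarray(mask.data if isinstance(mask, Volume) else mask) > 0
    if mask.shape != arr.shape[:-1]:
        raise ValueError(f"mask shape {mask.shape} vs data {arr.shape[:-1]}")
    return arr[mask], mask


def ols_fit(design: DesignMatrix, data: FmriSeries | np.ndarray,
            mask: np.ndarray | None = None) -> GlmFit:
    """Ordinary least squares per voxel with the shared pseudoinverse.

    sigma2 is the unbiased residual variance ||eps||^2 / (T - R).
    """
    X = design.X
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]})")
    y, mask = _masked_data(data, mask)
    if y.shape[1] != X.shape[0]:
        raise ValueError(f"{y.shape[1]} time points vs design {X.shape[0]}")
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    resid = y - beta @ X.T
    dof = X.shape[0] - X.shape[1]
    sigma2 = np.sum(resid ** 2, axis=1) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    return GlmFit(beta=beta, residuals=resid, sigma2=sigma2, design=design,
                  mask=mask, dof=dof, xtx_inv=xtx_inv)


def contrast_statistic(fit: GlmFit, design: DesignMatrix | None = None,
                       kind: str = "t") -> np.ndarray:
    """t = (c^T beta - u) / sqrt(var(eps) c^T (X^T X)^(-1) c), or the
    F analogue with a contrast matrix C (divided by the number of contrast
    rows N). Whitened fits use the voxel-specific whitened design.

    Returns per-voxel statistic values (V,); use fit.unmask for a volume.
    """
    design = design or fit.design
    C = design.contrast
    if C is None:
        raise ValueError("design has no contrast")
    C = np.atleast_2d(C)
    u = np.atleast_1d(np.asarray(design.null_value, float))
    if u.size == 1:
        u = np.full(C.shape[0], float(u[0]))
    effect = fit.beta @ C.T - u[None, :]
    if fit.xtx_inv is None:
        raise ValueError("fit carries no (X^T X)^(-1)")
    if kind == "t":
        if C.shape[0] != 1:
            raise ValueError("t statistic needs a single contrast row")
        c = C[0]
        if fit.xtx_inv.ndim == 2:
            quad = float(c @ fit.xtx_inv @ c)
            denom2 = fit.sigma2 * quad
        else:
            quad = np.einsum("i,vij,j->v", c, fit.xtx_inv, c)
            denom2 = fit.sigma2 * quad
        if np.any(denom2 <= 0):
            bad = int(np.count_nonzero(denom2 <= 0))
            if fit.xtx_inv.ndim == 2 and quad <= 0:
                raise FloatingPointError("c^T (X^T X)^(-1) c is not positive")
            denom2 = np.where(denom2 <= 0, np.inf, denom2)
        return effect[:, 0] / np.sqrt(denom2)
    if kind == "F":
        N = C.shape[0]
        if fit.xtx_inv.ndim == 2:
            mid = C @ fit.xtx_inv @ C.T  # (N, N)
            mid_inv = np.linalg.inv(mid)
            quad = np.einsum("vi,ij,vj->v", effect, mid_inv, effect)
            return quad / (fit.sigma2 * N)
        mid = np.einsum("ai,vij,bj->vab", C, fit.xtx_inv, C)
        quad = np.einsum("va,vab,vb->v", effect, np.linalg.inv(mid), effect)
        return quad / (fit.sigma2 * N)
    raise ValueError(f"kind must be 't' or 'F', got {kind!r}")


def residual_autocov_correction(X: np.ndarray, order: int) -> np.ndarray:
    """Bias matrix M relating true to residual autocovariances.

    OLS residuals r = (I - H) eps deflate (and for the low frequencies a
    design absorbs, distort) sample autocovariances: with c_k the lag-k
    residual autocovariance (sum / T), E[c_k] = sum_l M_kl gamma_l where
    gamma_l is the true error autocovariance. M depends only on the design,
    so it is computed once and c is corrected by M^(-1).
    """
    T = X.shape[0]
    A = np.eye(T) - X @ np.linalg.pinv(X)
    M = np.empty((order + 1, order + 1))
    idx = np.arange(T)
    for k in range(order + 1):
        sym = np.zeros((T, T))
        if k == 0:
            sym[idx, idx] = 1.0
        else:
            sym[idx[:-k], idx[k:]] = 0.5
            sym[idx[k:], idx[:-k]] += 0.5
        asa = A @ sym @ A
        for l in range(order + 1):
            if l == 0:
                M[k, l] = np.trace(asa) / T
            else:
                M[k, l] = 2.0 * np.sum(asa[idx[:-l], idx[l:]]) / T
    return M


def estimate_ar_yule_walker(residuals: np.ndarray, order: int = 4,
                            design: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel AR coefficients from the Toeplitz Yule-Walker system built
    on biased sample autocovariances (normalized by T).

    With ``design`` given, the autocovariances are first corrected for the
    deflation the OLS residual projection induces (residual_autocov_
    correction) — without it the detrend columns alias low-frequency noise
    power into negatively biased AR estimates.

    residuals: (V, T); returns (V, order). Zero-variance voxels get rho = 0.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    resid = np.atleast_2d(np.asarray(residuals, float))
    V, T = resid.shape
    if T <= 5 * order:
        raise ValueError(f"need T > {5 * order} time points for AR({order})")
    centered = resid - resid.mean(axis=1, keepdims=True)
    acov = np.empty((V, order + 1))
    for lag in range(order + 1):
        acov[:, lag] = np.sum(centered[:, lag:] * centered[:, :T - lag],
                              axis=1) / T
    if design is not None:
        M = residual_autocov_correction(np.asarray(design, float), order)
        acov = acov @ np.linalg.inv(M).T
    rho = np.zeros((V, order))
    ok = acov[:, 0] > 0
    if order == 1:
        rho[ok, 0] = acov[ok, 1] / acov[ok, 0]
        return rho
    for v in np.nonzero(ok)[0]:
        try:
            rho[v] = solve_toeplitz(acov[v, :order], acov[v, 1:order + 1])
        except np.linalg.LinAlgError:
            pass
    return rho


def estimate_ar_spatial(residuals: np.ndarray, design: np.ndarray,
                        mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0),
                        order: int = 4, fwhm_mm: float = 7.0) -> np.ndarray:
    """AR estimation for whitening pipelines that need calibrated nulls.

    Sample autocovariances are corrected for the OLS residual-projection
    bias (residual_autocov_correction) and spatially smoothed (normalized
    averaging within the mask) BEFORE the Yule-Walker solve — solving on
    low-noise averaged autocovariances sidesteps the small-sample ratio
    bias that per-voxel solves incur. Returns (V, order).
    """
    resid = np.atleast_2d(np.asarray(residuals, float))
    V, T = resid.shape
    acov = np.empty((V, order + 1))
    for lag in range(order + 1):
        acov[:, lag] = np.sum(resid[:, lag:] * resid[:, :T - lag], axis=1) / T
    M = residual_autocov_correction(np.asarray(design, float), order)
    acov = acov @ np.linalg.inv(M).T
    if fwhm_mm > 0:
        cert = mask.astype(float)
        for lag in range(order + 1):
            grid = np.zeros(mask.shape)
            grid[mask] = acov[:, lag]
            sm = smooth_normalized(Volume(grid, voxel_size=voxel_size),
                                   cert, fwhm_mm)
            acov[:, lag] = sm.data[mask]
    rho = np.zeros((V, order))
    for v in range(V):
        if acov[v, 0] > 0:
            try:
                rho[v] = solve_toeplitz(acov[v, :order], acov[v, 1:order + 1])
            except np.linalg.LinAlgError:
                pass
    return rho


def whiten_series(y: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """y~_t = y_t - sum_i rho_i y_{t-i} with zero initial conditions.

    Works on (..., T) data against (..., p) coefficients (broadcast on the
    leading axes); output keeps length T.
    """
    y = np.asarray(y, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    p = rho.shape[-1]
    out = y.copy()
    for i in range(1, p + 1):
        shifted = np.zeros_like(y)
        shifted[..., i:] = y[..., :-i]
        out -= rho[..., i - 1:i] * shifted if rho.ndim == y.ndim else \
            rho[..., i - 1, None] * shifted
    return out


def unwhiten_series(w: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Run the AR recursion forward: y_t = w_t + sum_i rho_i y_{t-i} (zero
    initial conditions) — the exact inverse of whiten_series."""
    w = np.asarray(w, dtype=np.float64)
    rho = np.atleast_2d(np.asarray(rho, dtype=np.float64))
    p = rho.shape[-1]
    y = np.array(w, dtype=np.float64)
    T = y.shape[-1]
    for t in range(T):
        for i in range(1, min(p, t) + 1):
            y[..., t] += rho[..., i - 1] * y[..., t - i]
    return y


def cochrane_orcutt_fit(design: DesignMatrix, data: FmriSeries | np.ndarray,
                        mask: np.ndarray | None = None, order: int = 4,
                        iterations: int = 3, ar_smooth_fwhm_mm: float = 7.0,
                        voxel_size=(1.0, 1.0, 1.0)) -> GlmFit:
    """Iterative prewhitened GLM fit.

    Each round: estimate AR(order) on residuals of the current beta computed
    against the ORIGINAL y and X, smooth each AR coefficient map spatially
    (7 mm normalized averaging within the mask), whiten y and every design
    column per voxel, and re-estimate beta from the whitened quantities.
    After the final round the statistics use var of the whitened residuals
    and the voxel-specific whitened (X~^T X~)^(-1). ``iterations=0``
    reproduces plain OLS.
    """
    fit = ols_fit(design, data, mask)
    if iterations == 0:
        return fit
    X = design.X
    y, mask_b = _masked_data(data, mask)
    is_spatial = isinstance(data, FmriSeries) or (
        hasattr(data, "ndim") and np.asarray(data).ndim == 4)
    if isinstance(data, FmriSeries):
        voxel_size = data.voxel_size
    beta = fit.beta
    rho_s = None
    xtx_inv = None
    resid_w = None
    sigma2 = None
    for _ in range(iterations):
        resid = y - beta @ X.T  # original y and X, newest beta
        rho = estimate_ar_yule_walker(resid, order=order)
        if is_spatial and ar_smooth_fwhm_mm > 0:
            rho_s = np.empty_like(rho)
            cert = mask_b.astype(float)
            for i in range(order):
                grid = np.zeros(mask_b.shape)
                grid[mask_b] = rho[:, i]
                sm = smooth_normalized(Volume(grid, voxel_size=voxel_size),
                                       cert, ar_smooth_fwhm_mm)
                rho_s[:, i] = sm.data[mask_b]
        else:
            rho_s = rho
        yw = whiten_series(y, rho_s)
        # whiten every design column per voxel: Xw is (V, T, R)
        Xw = np.empty((y.shape[0], X.shape[0], X.shape[1]))
        for r in range(X.shape[1]):
            Xw[:, :, r] = whiten_series(
                np.broadcast_to(X[:, r], y.shape), rho_s)
        xtx = np.einsum("vtr,vts->vrs", Xw, Xw)
        xty = np.einsum("vtr,vt->vr", Xw, yw)
        beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
        resid_w = yw - np.einsum("vtr,vr->vt", Xw, beta)
        xtx_inv = np.linalg.inv(xtx)
    dof = X.shape[0] - X.shape[1]
    sigma2 = np.sum(resid_w ** 2, axis=1) / dof
    return GlmFit(beta=beta, residuals=resid_w, sigma2=sigma2, design=design,
                  mask=mask_b, dof=dof, rho=rho_s, xtx_inv=xtx_inv)
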