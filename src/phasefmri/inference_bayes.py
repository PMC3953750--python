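"""Bayesian GLM with AR(1) errors via Gibbs sampling.

Per voxel the model is y = X beta + eps with eps_t = rho eps_{t-1} + w_t,
w_t ~ N(0, sigma2). Priors: beta | sigma2 Gaussian, rho Gaussian truncated
to (-1, 1), sigma2 inverse gamma. The sampler alternates three full
conditionals — sigma2 | rho (inverse gamma, with beta marginalized out),
beta | sigma2, rho (multivariate Gaussian) and rho | beta, sigma2
(Gaussian, rejected outside the stationarity region) — each conditioning on
the most recently simulated values. The posterior probability map (PPM) is
the fraction of retained draws with c^T beta > 0.

Whitened cross-products are never recomputed from the series: with
rho_0 = -1 they separate into rho-independent data moments

    X~^T X~ = sum_ij rho_i rho_j S_ij,   S_ij = sum_t x_{t-i} x_{t-j}^T

(and analogous m_ij = sum_t x_{t-i} y_{t-j}, g_ij = sum_t y_{t-i} y_{t-j}),
so each rho update costs a handful of small matrix combinations. Residual
lag sums for the rho update come from the same moments.

Random numbers use a counter-based Philox stream for uniforms; normals come
from the Box-Muller transform and inverse-gamma draws from
g = 2B / sum_{i=1}^{2A} n_i^2, which requires 2A to be a positive integer —
prior shapes are validated against this restriction rather than silently
substituting another sampler.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import FmriSeries
from . import glm as glm_mod


@dataclasses.dataclass
class SufficientStats:
    """Data moments for lags 0..order with the convention rho_0 = -1.

    S[i][j]: (R, R); m[i][j]: (V, R); g[i][j]: (V,). Lagged samples with
    t <= 0 are zero (consistent with the whitening initial conditions).
    """

    S: list[list[np.ndarray]]
    m: list[list[np.ndarray]]
    g: list[list[np.ndarray]]
    order: int
    n_timepoints: int


def _lagged(a: np.ndarray, lag: int) -> np.ndarray:
    """Shift along the first axis, zero-filling (x_t = 0 for t <= 0)."""
    if lag == 0:
        return a
    out = np.zeros_like(a)
    out[lag:] = a[:-lag]
    return out


def precompute_suffstats(design: glm_mod.DesignMatrix | np.ndarray,
                         y: np.ndarray, order: int = 1) -> SufficientStats:
    """All S_ij, m_ij, g_ij for i, j in 0..order; y is (V, T) or (T,)."""
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    X = design.X if isinstance(design, glm_mod.DesignMatrix) else np.asarray(design, float)
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))  # (V, T)
    T = X.shape[0]
    if y.shape[1] != T:
        raise ValueError(f"y has {y.shape[1]} time points, design has {T}")
    if T <= order:
        raise ValueError("need more time points than the AR order")
    Xl = [_lagged(X, i) for i in range(order + 1)]
    yl = [_lagged(y.T, i).T for i in range(order + 1)]  # each (V, T)
    S = [[Xl[i].T @ Xl[j] for j in range(order + 1)] for i in range(order + 1)]
    m = [[yl[j] @ Xl[i] for j in range(order + 1)] for i in range(order + 1)]
    g = [[np.sum(yl[i] * yl[j], axis=1) for j in range(order + 1)]
         for i in range(order + 1)]
    return SufficientStats(S=S, m=m, g=g, order=order, n_timepoints=T)


def whitened_crossproducts(stats: SufficientStats, rho: np.ndarray | float,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X~^T X~, X~^T y~, y~^T y~) from the moments, with rho_0 = -1.

    rho may be scalar/(order,) shared across voxels or (V, order) voxel-wise.
    For order 1 the design part reduces to S00 - 2 rho S01 + rho^2 S11.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=np.float64))
    voxelwise = rho.ndim == 2
    p = stats.order
    if (rho.shape[-1] if rho.ndim else 1) != p:
        raise ValueError(f"need {p} AR coefficients, got {rho.shape}")
    V = stats.g[0][0].shape[0]
    coef = np.empty((V, p + 1)) if voxelwise else np.empty(p + 1)
    if voxelwise:
        coef[:, 0] = -1.0
        coef[:, 1:] = rho
    else:
        coef[0] = -1.0
        coef[1:] = rho
    R = stats.S[0][0].shape[0]
    if voxelwise:
        xtx = np.zeros((V, R, R))
        xty = np.zeros((V, R))
        yty = np.zeros(V)
        for i in range(p + 1):
            for j in range(p + 1):
                cc = coef[:, i] * coef[:, j]
                xtx += cc[:, None, None] * stats.S[i][j][None, :, :]
                xty += cc[:, None] * stats.m[i][j]
                yty += cc * stats.g[i][j]
    else:
        xtx = np.zeros((R, R))
        xty = np.zeros((V, R))
        yty = np.zeros(V)
        for i in range(p + 1):
            for j in range(p + 1):
                cc = coef[i] * coef[j]
                xtx += cc * stats.S[i][j]
                xty += cc * stats.m[i][j]
                yty += cc * stats.g[i][j]
    return xtx, xty, yty


class PhaseRng:
    """Counter-based uniform stream (Philox) with Box-Muller normals and the
    sum-of-squared-normals inverse-gamma sampler."""

    def __init__(self, seed: int):
        self._gen = np.random.Generator(np.random.Philox(seed))

    def uniform(self, size=None) -> np.ndarray:
        return self._gen.random(size)

    def normal(self, size=None) -> np.ndarray:
        """Standard normals via the Box-Muller transform on uniform pairs."""
        n = int(np.prod(size)) if size is not None else 1
        half = (n + 1) // 2
        u1 = 1.0 - self.uniform(half)  # (0, 1] keeps log finite
        u2 = self.uniform(half)
        r = np.sqrt(-2.0 * np.log(u1))
        z = np.concatenate([r * np.cos(2.0 * np.pi * u2),
                            r * np.sin(2.0 * np.pi * u2)])[:n]
        if size is None:
            return float(z[0])
        return z.reshape(size)

    def invgamma(self, shape_a: float, scale_b, size=None) -> np.ndarray:
        """g = 2B / sum_{i=1}^{2A} n_i^2; 2A must be a positive integer."""
        two_a = 2.0 * shape_a
        if abs(two_a - round(two_a)) > 1e-9 or round(two_a) < 1:
            raise ValueError(
                f"inverse-gamma sampler requires 2A to be a positive integer, "
                f"got 2A = {two_a}")
        k = int(round(two_a))
        scale_b = np.asarray(scale_b, dtype=np.float64)
        n = int(np.prod(size)) if size is not None else 1
        normals = self.normal((n, k))
        denom = np.sum(normals ** 2, axis=1)
        out = 2.0 * scale_b.reshape(-1) / denom if scale_b.ndim else \
            2.0 * scale_b / denom
        if size is None:
            return float(out[0])
        return out.reshape(size)


def sample_distribution(kind: str, params: dict, n: int,
                        state: PhaseRng) -> np.ndarray:
    """Draw ``n`` values from uniform, normal (Box-Muller) or inverse gamma
    (the 2B / chi-square construction)."""
    if kind == "uniform":
        lo, hi = params.get("low", 0.0), params.get("high", 1.0)
        return lo + (hi - lo) * state.uniform(n)
    if kind == "normal":
        return params.get("mean", 0.0) + params.get("std", 1.0) * state.normal(n)
    if kind == "invgamma":
        return state.invgamma(params["shape"], params["scale"], n)
    raise ValueError(f"unknown distribution kind {kind!r}")


@dataclasses.dataclass
class PriorSpec:
    """Weakly informative defaults; a0 = 0.5 keeps 2(a0 + T/2) integral for
    the inverse-gamma sampler."""

    mu0: float | np.ndarray = 0.0
    omega0_scale: float = 1e-4     # Omega0 = omega0_scale * I (times 1/sigma2)
    a0: float = 0.5
    b0: float = 0.01
    v0: float = 1.0                # rho prior variance, support (-1, 1)

    def validate(self, n_timepoints: int) -> None:
        if self.a0 <= 0 or self.b0 <= 0 or self.v0 <= 0 or self.omega0_scale < 0:
            raise ValueError("prior hyperparameters must be positive")
        two_a = 2.0 * (self.a0 + n_timepoints / 2.0)
        if abs(two_a - round(two_a)) > 1e-9:
            raise ValueError(
                f"posterior shape a0 + T/2 = {self.a0 + n_timepoints / 2} is "
                "not half-integral; the inverse-gamma sampler requires 2A to "
                "be an integer (choose a0 with 2*a0 integral)")


@dataclasses.dataclass
class PosteriorDraws:
    """Post-burn-in chains and the derived posterior probability map."""

    beta: np.ndarray     # (V, n_kept, R)
    sigma2: np.ndarray   # (V, n_kept)
    rho: np.ndarray      # (V, n_kept)
    n_draws: int
    n_burnin: int
    mask: np.ndarray | None = None


def gibbs_fit(design: glm_mod.DesignMatrix, data: FmriSeries | np.ndarray,
              mask: np.ndarray | None = None, order: int = 1,
              n_draws: int = 11000, n_burnin: int = 1000,
              priors: PriorSpec | None = None,
              contrast: np.ndarray | None = None,
              seed: int = 0) -> PosteriorDraws:
    """Gibbs sampler for the GLM with AR(1) errors, vectorized over voxels.

    Per sweep: (1) sigma2 | rho from an inverse gamma with shape a0 + T/2
    and scale built from the beta-marginalized quadratic form; (2) beta |
    sigma2, rho Gaussian with precision (X~^T X~ + Omega0) / sigma2;
    (3) rho | beta, sigma2 Gaussian from the residual lag regression,
    rejected outside (-1, 1). All residual sums come from the precomputed
    moments, never from the raw series.
    """
    if order != 1:
        raise ValueError("only an AR(1) error model is supported")
    priors = priors or PriorSpec()
    X = design.X
    R = X.shape[1]
    if R > 8:
        raise ValueError(f"{R} regressors exceed the sampler's limit of 8")
    y, mask_b = glm_mod._masked_data(data, mask)
    V, T = y.shape
    priors.validate(T)
    if n_burnin >= n_draws:
        raise ValueError("n_burnin must be smaller than n_draws")

    stats = precompute_suffstats(design, y, order=1)
    omega0 = priors.omega0_scale * np.eye(R)
    rng = PhaseRng(seed)
    a_post = priors.a0 + T / 2.0

    rho = np.zeros(V)
    n_kept = n_draws - n_burnin
    beta_chain = np.empty((V, n_kept, R))
    sigma2_chain = np.empty((V, n_kept))
    rho_chain = np.empty((V, n_kept))

    for sweep in range(n_draws):
        xtx, xty, yty = whitened_crossproducts(stats, rho[:, None])
        lam = xtx + omega0[None, :, :]
        mu_n = np.linalg.solve(lam, xty[..., None])[..., 0]
        quad = yty - np.einsum("vr,vr->v", xty, mu_n)
        quad = np.maximum(quad, 1e-12)
        # (1) sigma2 | rho, beta marginalized
        sigma2 = rng.invgamma(a_post, priors.b0 + 0.5 * quad, size=V)
        # (2) beta | sigma2, rho
        cov = np.linalg.inv(lam) * sigma2[:, None, None]
        chol = np.linalg.cholesky(cov)
        beta = mu_n + np.einsum("vij,vj->vi", chol, rng.normal((V, R)))
        # (3) rho | beta, sigma2 from residual lag sums via the moments
        def esum(i: int, j: int) -> np.ndarray:
            return (stats.g[i][j]
                    - np.einsum("vr,vr->v", stats.m[i][j], beta)
                    - np.einsum("vr,vr->v", stats.m[j][i], beta)
                    + np.einsum("vr,rs,vs->v", beta, stats.S[i][j], beta))
        e11 = np.maximum(esum(1, 1), 1e-12)
        e01 = esum(0, 1)
        prec = e11 / sigma2 + 1.0 / priors.v0
        mean = (e01 / sigma2) / prec
        sd = 1.0 / np.sqrt(prec)
        proposal = mean + sd * rng.normal(V)
        ok = np.abs(proposal) < 1.0
        for _ in range(50):
            if ok.all():
                break
            redraw = mean + sd * rng.normal(V)
            take = ~ok & (np.abs(redraw) < 1.0)
            proposal[take] = redraw[take]
            ok |= take
        rho = np.where(ok, proposal, rho)
        if sweep >= n_burnin:
            k = sweep - n_burnin
            beta_chain[:, k, :] = beta
            sigma2_chain[:, k] = sigma2
            rho_chain[:, k] = rho
    return PosteriorDraws(beta=beta_chain, sigma2=sigma2_chain,
                          rho=rho_chain, n_draws=n_draws, n_burnin=n_burnin,
                          mask=mask_b)


def compute_ppm(draws: PosteriorDraws,
                contrast: np.ndarray | None = None) -> np.ndarray:
    """Pr(c^T beta > 0) per voxel from the retained draws."""
    if draws.beta.shape[1] == 0:
        raise ValueError("no post-burn-in draws")
    R = draws.beta.shape[2]
    c = np.zeros(R)
    if contrast is None:
        c[0] = 1.0
    else:
        contrast = np.asarray(contrast, dtype=np.float64).reshape(-1)
        c[:contrast.size] = contrast
    effect = draws.beta @ c
    return (effect > 0).mean(axis=1)
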