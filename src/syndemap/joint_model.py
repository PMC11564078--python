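"""Shared-component Poisson model for censored multi-disease areal counts.

The model: counts Y_dit ~ Poisson(E_dit * theta_dit) with

    log theta_dit = alpha_d + x_i' beta_d + delta_d * phi_i + psi_di
                    + gamma_d * (t - t_bar)

where phi is a latent spatial field shared by all diseases (zero-mean
Gaussian process, exponential covariance sigma2_phi * exp(-h/rho_phi) over
unit centroids), psi_d are disease-specific fields, and the positive
loadings delta_d are constrained to product 1 (log-deltas sum to zero) so
that the shared field's scale is identified.

Confidentiality-censored cells, known only as an integer interval [lo, hi],
are handled by data augmentation: each sweep draws the censored count
exactly from the Poisson distribution truncated to its interval (the support
is tiny, so finite enumeration is exact), after which every block sees a
complete Poisson panel.

Sampler blocks (Metropolis-within-Gibbs):
  (a) censored-cell imputation (exact truncated-Poisson draw);
  (b) per-disease (alpha_d, beta_d, gamma_d) random-walk Metropolis with
      step-size adaptation during burn-in only;
  (c) phi and each psi_d by elliptical slice sampling under their GP priors,
      plus a joint field/variance rescaling move that breaks the
      variance-amplitude funnel;
  (d) log delta by random walk on the sum-zero subspace;
  (e) covariance parameters by Metropolis on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .geo_synth import CensoredCount, CountPanel, Geography

__all__ = [
    "ModelSpec", "PosteriorSamples", "RiskSurface",
    "censored_poisson_loglik", "sample_truncated_poisson",
    "run_mcmc", "summarize_risk", "cumulative_risk", "downscale_to_fine",
    "mediation_scan", "rhat", "effective_sample_size",
]


# ---------------------------------------------------------------------------
# Censored Poisson likelihood and truncated sampling
# ---------------------------------------------------------------------------


def censored_poisson_loglik(cell, mu) -> float | np.ndarray:
    """Log-likelihood of a possibly censored count under Poisson(mu).

    ``cell`` may be a :class:`CensoredCount` or a ``(lo, hi)`` bounds pair
    (arrays allowed; ``lo == hi`` means observed, ``hi = inf`` means a
    right-open interval).  Interval cells contribute
    ``log sum_{k=lo..hi} Poisson(k; mu)`` computed stably.
    """
    if isinstance(cell, CensoredCount):
        lo, hi = cell.bounds()
    else:
        lo, hi = cell
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    mu = np.asarray(mu, float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    lo_b, hi_b, mu_b = np.broadcast_arrays(lo, hi, mu)
    out = np.empty(lo_b.shape)
    obs = lo_b == hi_b
    if obs.any():
        out[obs] = poisson.logpmf(lo_b[obs], mu_b[obs])
    unb = (~obs) & np.isinf(hi_b)
    if unb.any():
        # mass of [lo, inf) = survival beyond lo-1
        out[unb] = poisson.logsf(lo_b[unb] - 1, mu_b[unb])
    bnd = (~obs) & ~np.isinf(hi_b)
    if bnd.any():
        lo_i = lo_b[bnd].astype(int)
        hi_i = hi_b[bnd].astype(int)
        mu_i = mu_b[bnd]
        width = int((hi_i - lo_i).max()) + 1
        ks = lo_i[:, None] + np.arange(width)[None, :]
        valid = ks <= hi_i[:, None]
        logpmf = ks * np.log(mu_i[:, None]) - mu_i[:, None] - gammaln(ks + 1.0)
        logpmf = np.where(valid, logpmf, -np.inf)
        out[bnd] = logsumexp(logpmf, axis=1)
    if out.shape == ():
        return float(out)
    return out


def sample_truncated_poisson(mu: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Exact draws from Poisson(mu) truncated to the integer interval [lo, hi].

    Finite supports are enumerated (exact inverse-cdf via Gumbel-max);
    ``hi = inf`` cells fall back to untruncated Poisson draws shifted into
    [lo, inf) by rejection-free inverse cdf.
    """
    mu = np.asarray(mu, float)
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    out = np.empty(mu.shape, dtype=np.int64)
    unb = np.isinf(hi)
    if unb.any():
        # inverse-cdf on the conditional distribution given k >= lo
        u = rng.uniform(size=unb.sum())
        p_lo = poisson.cdf(lo[unb] - 1, mu[unb])
        q = p_lo + u * (1 - p_lo)
        out[unb] = poisson.ppf(np.minimum(q, 1 - 1e-16), mu[unb]).astype(np.int64)
        out[unb] = np.maximum(out[unb], lo[unb].astype(np.int64))
    fin = ~unb
    if fin.any():
        lo_i = lo[fin].astype(int)
        hi_i = hi[fin].astype(int)
        mu_i = mu[fin]
        width = int((hi_i - lo_i).max()) + 1
        ks = lo_i[:, None] + np.arange(width)[None, :]
        valid = ks <= hi_i[:, None]
        logpmf = ks * np.log(mu_i[:, None]) - mu_i[:, None] - gammaln(ks + 1.0)
        logpmf = np.where(valid, logpmf, -np.inf)
        gum = rng.gumbel(size=logpmf.shape)
        pick = (logpmf + gum).argmax(axis=1)
        out[fin] = ks[np.arange(len(lo_i)), pick]
    return out


# ---------------------------------------------------------------------------
# Model specification and posterior container
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Priors and MCMC settings for :func:`run_mcmc`.

    Priors (weakly informative defaults; none are stated by the analysis
    this emulates): alpha, beta, gamma ~ N(0, prior_sd^2); log delta ~
    N(0, 1) on the sum-zero subspace; sigma^2 ~ half-Normal(0, 1); rho ~
    Uniform(rho_bounds), defaulting to (0.5 km, 2 x max inter-unit
    distance).  Setting ``sigma2_phi_fixed=0`` (resp. psi) pins the field to
    zero, which reduces the model to independent Poisson regressions.
    """

    n_iter: int = 3000
    burn_in: int = 1000
    thinning: int = 2
    n_chains: int = 1
    seed: int = 0
    prior_sd: float = 10.0
    delta_log_sd: float = 1.0
    sigma2_half_normal_scale: float = 1.0
    rho_bounds: tuple[float, float] | None = None
    covariance: str = "exponential"
    include_specific_field: bool = True
    include_time_trend: bool = True
    psi_nugget: float = 0.0
    sigma2_phi_fixed: float | None = None
    rho_phi_fixed: float | None = None
    sigma2_psi_fixed: float | None = None
    rho_psi_fixed: float | None = None
    delta_fixed: bool = False      # pin all loadings at 1 (independent-style fit)

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.covariance != "exponential":
            raise ValueError("only the exponential covariance family is supported")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws for every model parameter and imputed count."""

    units: list[str]
    diseases: list[str]
    periods: list[int]
    covariate_names: list[str]
    alpha: np.ndarray        # (S, D)
    beta: np.ndarray         # (S, D, p)
    gamma: np.ndarray        # (S, D)
    delta: np.ndarray        # (S, D)
    phi: np.ndarray          # (S, U)
    psi: np.ndarray          # (S, U, D)
    sigma2_phi: np.ndarray   # (S,)
    rho_phi: np.ndarray
    sigma2_psi: np.ndarray
    rho_psi: np.ndarray
    imputed: np.ndarray      # (S, C) imputed censored counts
    cens_index: np.ndarray   # (C, 3) (unit, disease, period) indices
    chain: np.ndarray        # (S,)
    acceptance: dict
    X: np.ndarray            # (U, p) standardized design used in the fit
    x_center: np.ndarray
    x_scale: np.ndarray
    t_centered: np.ndarray   # (T,)

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    def log_theta(self, s: int) -> np.ndarray:
        """Log relative risk (U, D, T) for draw s."""
        c = (self.alpha[s][None, :] + self.X @ self.beta[s].T
             + self.delta[s][None, :] * self.phi[s][:, None] + self.psi[s])
        g = self.gamma[s][:, None] * self.t_centered[None, :]
        return c[:, :, None] + g[None, :, :]

    def latent_field(self, s: int) -> np.ndarray:
        """Shared + specific latent spatial component (U, D) for draw s."""
        return self.delta[s][None, :] * self.phi[s][:, None] + self.psi[s]

    def mu(self, s: int, panel: CountPanel) -> np.ndarray:
        return panel.expected * np.exp(self.log_theta(s))

    def theta_draws(self) -> np.ndarray:
        """(S, U, D, T) relative-risk draws (materialised; use with care)."""
        return np.stack([np.exp(self.log_theta(s)) for s in range(self.n_draws)])

    def save(self, prefix) -> None:
        """Write draws as a columnar CSV (one row per draw per parameter)
        plus a JSON sidecar with the indexing metadata."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        frame_cols: dict[str, np.ndarray] = {}
        S, D = self.alpha.shape
        p = self.beta.shape[2]
        U = len(self.units)
        for d in range(D):
            frame_cols[f"alpha[{d}]"] = self.alpha[:, d]
            frame_cols[f"gamma[{d}]"] = self.gamma[:, d]
            frame_cols[f"delta[{d}]"] = self.delta[:, d]
            for j in range(p):
                frame_cols[f"beta[{d},{j}]"] = self.beta[:, d, j]
        for i in range(U):
            frame_cols[f"phi[{i}]"] = self.phi[:, i]
        for i in range(U):
            for d in range(D):
                frame_cols[f"psi[{i},{d}]"] = self.psi[:, i, d]
        for name in ("sigma2_phi", "rho_phi", "sigma2_psi", "rho_psi"):
            frame_cols[name] = getattr(self, name)
        for k in range(self.imputed.shape[1]):
            frame_cols[f"imputed[{k}]"] = self.imputed[:, k]
        long = pd.DataFrame(frame_cols)
        long.insert(0, "chain", self.chain)
        long.insert(1, "draw", np.arange(S))
        long = long.melt(id_vars=["chain", "draw"], var_name="parameter")
        long.to_csv(f"{prefix}.draws.csv", index=False)
        meta = {
            "units": self.units, "diseases": self.diseases,
            "periods": self.periods, "covariate_names": self.covariate_names,
            "X": self.X.tolist(), "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "t_centered": self.t_centered.tolist(),
            "cens_index": self.cens_index.tolist(),
            "acceptance": self.acceptance,
        }
        Path(f"{prefix}.meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, prefix) -> "PosteriorSamples":
        import json
        from pathlib import Path

        meta = json.loads(Path(f"{prefix}.meta.json").read_text())
        long = pd.read_csv(f"{prefix}.draws.csv")
        wide = long.pivot(index=["chain", "draw"], columns="parameter",
                          values="value").reset_index()
        S = len(wide)
        U = len(meta["units"])
        D = len(meta["diseases"])
        p = len(meta["covariate_names"])
        cens = np.array(meta["cens_index"], dtype=int).reshape(-1, 3)

        def grab(fmt, shape):
            out = np.empty((S,) + shape)
            for idx in np.ndindex(shape):
                out[(slice(None),) + idx] = wide[fmt.format(*idx)].to_numpy()
            return out

        return cls(
            units=meta["units"], diseases=meta["diseases"],
            periods=meta["periods"], covariate_names=meta["covariate_names"],
            alpha=grab("alpha[{}]", (D,)), beta=grab("beta[{},{}]", (D, p)),
            gamma=grab("gamma[{}]", (D,)), delta=grab("delta[{}]", (D,)),
            phi=grab("phi[{}]", (U,)), psi=grab("psi[{},{}]", (U, D)),
            sigma2_phi=wide["sigma2_phi"].to_numpy(),
            rho_phi=wide["rho_phi"].to_numpy(),
            sigma2_psi=wide["sigma2_psi"].to_numpy(),
            rho_psi=wide["rho_psi"].to_numpy(),
            imputed=(grab("imputed[{}]", (len(cens),)).astype(np.int64)
                     if len(cens) else np.empty((S, 0), dtype=np.int64)),
            cens_index=cens, chain=wide["chain"].to_numpy(int),
            acceptance=meta["acceptance"],
            X=np.array(meta["X"], float).reshape(U, p),
            x_center=np.array(meta["x_center"], float),
            x_scale=np.array(meta["x_scale"], float),
            t_centered=np.array(meta["t_centered"], float),
        )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def rhat(draws: np.ndarray, chain: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction over the given chain labels.

    Each chain is additionally split in half, per current practice.
    """
    chains = []
    for c in np.unique(chain):
        x = draws[chain == c]
        h = len(x) // 2
        if h >= 2:
            chains.extend([x[:h], x[h:2 * h]])
    if len(chains) < 2:
        return float("nan")
    n = min(len(c) for c in chains)
    arr = np.stack([c[:n] for c in chains])
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (n * w)))


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS from the initial positive sequence of autocorrelations."""
    x = np.asarray(draws, float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    # Geyer: sum consecutive pairs while their sum stays positive
    tau = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair < 0:
            break
        tau += 2 * pair
    return float(n / max(tau, 1.0))


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


def _chol_corr(dist: np.ndarray, rho: float, nugget: float) -> np.ndarray:
    r = np.exp(-dist / rho)
    r = r + (nugget + 1e-9) * np.eye(len(dist))
    return np.linalg.cholesky(r)


class _GP:
    """Exponential-correlation GP prior with cached Cholesky pieces.

    Caches L, L^-1 and log|R| so prior evaluations inside the sampler are
    plain matmuls, and R^-1 V for a fixed direction matrix V so the
    translation moves only need rank-one quadratic updates.
    """

    def __init__(self, dist: np.ndarray, rho: float, nugget: float,
                 directions: np.ndarray | None = None):
        self.L = _chol_corr(dist, rho, nugget)
        n = len(self.L)
        from scipy.linalg import solve_triangular
        self.Linv = solve_triangular(self.L, np.eye(n), lower=True,
                                     check_finite=False)
        self.logdetR = 2.0 * float(np.sum(np.log(np.diag(self.L))))
        self.W = self.Linv.T @ (self.Linv @ directions) \
            if directions is not None else None  # R^-1 V

    def logpdf(self, x2d: np.ndarray, sigma2: float) -> float:
        x2d = np.atleast_2d(x2d.T).T
        u, m = x2d.shape
        w = self.Linv @ x2d
        return -0.5 * (float((w * w).sum()) / sigma2
                       + m * (self.logdetR + u * math.log(sigma2)))

    def quad_shift(self, x: np.ndarray, v_idx: int, v: np.ndarray,
                   c: float, sigma2: float) -> float:
        """log-prior change replacing x by x - c*v (same sigma2, same R)."""
        w = self.W[:, v_idx]
        dquad = (-2.0 * c * float(x @ w) + c * c * float(v @ w)) / sigma2
        return -0.5 * dquad


class _AdaptiveScale:
    """Batch Robbins-Monro step-size adaptation, frozen after burn-in."""

    def __init__(self, init: float = 0.1, target: float = 0.3, batch: int = 20):
        self.log_s = math.log(init)
        self.target = target
        self.batch = batch
        self.acc = 0
        self.tries = 0
        self.total_acc = 0
        self.total = 0
        self.frozen = False

    @property
    def scale(self) -> float:
        return math.exp(self.log_s)

    def update(self, accepted: bool) -> None:
        self.total += 1
        self.total_acc += accepted
        if self.frozen:
            return
        self.tries += 1
        self.acc += accepted
        if self.tries >= self.batch:
            rate = self.acc / self.tries
            self.log_s += 0.8 * (rate - self.target)
            self.log_s = min(max(self.log_s, -12.0), 6.0)
            self.acc = 0
            self.tries = 0

    @property
    def rate(self) -> float:
        return self.total_acc / max(self.total, 1)


def _sum_zero_basis(d: int) -> np.ndarray:
    """Orthonormal basis (d x d-1) of the sum-zero subspace of R^d."""
    a = np.eye(d) - np.full((d, d), 1.0 / d)
    u, s, _ = np.linalg.svd(a)
    return u[:, :d - 1]


def run_mcmc(
    panel: CountPanel,
    selected_covariates: Sequence[str] | np.ndarray | None,
    geo: Geography,
    spec: ModelSpec,
    standardize: bool = False,
) -> PosteriorSamples:
    """Fit the shared-component model by Metropolis-within-Gibbs MCMC.

    ``selected_covariates`` is a list of column names of
    ``panel.covariates`` (e.g. the stepwise-selected set), a ready (U, p)
    matrix, or None for all panel covariates.  Covariates are expected
    standardized (pass ``standardize=True`` to have it done here, in which
    case the reported coefficients are on the standardized scale).  Multiple
    chains run sequentially from seeds derived from ``spec.seed``; draws are
    concatenated with a chain label.
    """
    U, D, T = panel.shape
    if isinstance(selected_covariates, np.ndarray):
        X_raw = np.asarray(selected_covariates, float)
        names = [f"x{j + 1}" for j in range(X_raw.shape[1])]
    elif selected_covariates is None:
        X_raw = panel.covariates.to_numpy(float) if len(panel.covariates) else np.empty((U, 0))
        names = list(panel.covariates.columns)
    else:
        names = list(selected_covariates)
        X_raw = panel.covariates[names].to_numpy(float)
    p = X_raw.shape[1]
    if p and standardize:
        x_center = X_raw.mean(axis=0)
        x_scale = np.where(X_raw.std(axis=0) > 0, X_raw.std(axis=0), 1.0)
    else:
        x_center = np.zeros(p)
        x_scale = np.ones(p)
    X = (X_raw - x_center) / x_scale if p else X_raw

    coords = geo.centroids(panel.level)
    order = {u: i for i, u in enumerate(geo.unit_ids(panel.level))}
    coords = coords[[order[u] for u in panel.units]]
    dist = cdist(coords, coords)
    max_dist = float(dist.max()) if U > 1 else 1.0
    # ranges beyond ~half the domain are indistinguishable from a constant
    # field, which only confounds the intercepts; keep the prior there
    rho_lo, rho_hi = spec.rho_bounds or (0.5, 0.5 * max(max_dist, 1.0))

    t_idx = np.arange(1, T + 1, dtype=float)
    t_c = t_idx - t_idx.mean()
    E = panel.expected
    logE = np.log(E)
    lo_b, hi_b = panel.bounds()
    cens = np.argwhere(np.isnan(panel.value))
    C = len(cens)
    ci, cd, ct = (cens[:, 0], cens[:, 1], cens[:, 2]) if C else (np.array([], int),) * 3
    c_lo = lo_b[ci, cd, ct] if C else np.empty(0)
    c_hi = hi_b[ci, cd, ct] if C else np.empty(0)

    fully_censored = [panel.diseases[d] for d in range(D)
                      if np.all(np.isnan(panel.value[:, d, :]))]
    if fully_censored:
        import warnings
        warnings.warn(f"diseases with no observed cells: {fully_censored}; "
                      "their intercepts are prior-driven", stacklevel=2)

    sample_phi = spec.sigma2_phi_fixed is None or spec.sigma2_phi_fixed > 0
    phi_var_fixed = spec.sigma2_phi_fixed is not None
    use_psi = spec.include_specific_field and (
        spec.sigma2_psi_fixed is None or spec.sigma2_psi_fixed > 0)
    psi_var_fixed = spec.sigma2_psi_fixed is not None
    use_time = spec.include_time_trend
    sample_delta = (not spec.delta_fixed) and D > 1 and sample_phi
    B_delta = _sum_zero_basis(D) if D > 1 else np.zeros((1, 0))

    n_keep = (spec.n_iter - spec.burn_in) // spec.thinning
    S_total = n_keep * spec.n_chains
    store = {
        "alpha": np.empty((S_total, D)), "beta": np.empty((S_total, D, p)),
        "gamma": np.empty((S_total, D)), "delta": np.empty((S_total, D)),
        "phi": np.empty((S_total, U)), "psi": np.empty((S_total, U, D)),
        "sigma2_phi": np.empty(S_total), "rho_phi": np.empty(S_total),
        "sigma2_psi": np.empty(S_total), "rho_psi": np.empty(S_total),
        "imputed": np.empty((S_total, C), dtype=np.int64),
        "chain": np.empty(S_total, dtype=int),
    }
    acceptance: dict[str, float] = {}

    for chain_id in range(spec.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed) % (2**31), chain_id]))

        # --- state initialisation
        y = panel.midpoint_filled().round()
        with np.errstate(divide="ignore"):
            alpha = np.log(np.maximum(y.sum(axis=(0, 2)), 0.5) / E.sum(axis=(0, 2)))
        beta = np.zeros((D, p))
        gamma = np.zeros(D)
        u_delta = np.zeros(max(D - 1, 0))
        delta = np.ones(D)
        phi = np.zeros(U)
        psi = np.zeros((U, D))
        sigma2_phi = spec.sigma2_phi_fixed if phi_var_fixed else 0.2
        rho_phi = spec.rho_phi_fixed if spec.rho_phi_fixed is not None else \
            float(np.median(dist[dist > 0])) if U > 1 else 1.0
        sigma2_psi = spec.sigma2_psi_fixed if psi_var_fixed else 0.1
        rho_psi = spec.rho_psi_fixed if spec.rho_psi_fixed is not None else rho_phi
        V_dir = np.column_stack([np.ones(U)] + ([X] if p else []))
        gp_phi = _GP(dist, rho_phi, 0.0, V_dir) if sample_phi else None
        gp_psi = _GP(dist, rho_psi, spec.psi_nugget, V_dir) if use_psi else None

        # maintained sufficient pieces
        S_ud = y.sum(axis=2)                    # (U, D)
        Yt_dt = y.sum(axis=0)                   # (D, T)
        g = (gamma[:, None] * t_c[None, :]) if use_time else np.zeros((D, T))
        Eg = np.einsum("udt,dt->ud", E, np.exp(g))   # (U, D)

        def c_field():
            return (alpha[None, :] + (X @ beta.T if p else 0.0)
                    + delta[None, :] * phi[:, None] + psi)

        def ll_c(cmat, cols=slice(None)):
            """Poisson log-lik (up to y!-const) as a function of the c-field."""
            return float(np.sum(S_ud[:, cols] * cmat - np.exp(cmat) * Eg[:, cols]))

        def ll_disease(d, a, b_vec, gam):
            cd_ = a + (X @ b_vec if p else 0.0) + delta[d] * phi + psi[:, d]
            gd = gam * t_c if use_time else np.zeros(T)
            m = np.exp(cd_) @ (E[:, d, :] @ np.exp(gd))
            return float(S_ud[:, d] @ cd_ + Yt_dt[d] @ gd - m)

        # Fisher-information preconditioner for the fixed-effect proposals:
        # per disease, chol of the inverse Poisson-GLM information at the
        # initial intensity, so the random walk matches the posterior scale.
        nprop0 = 1 + p + (1 if use_time else 0)
        prop_chol = []
        for d in range(D):
            cols = [np.ones(U * T)]
            if p:
                cols.append(np.repeat(X, T, axis=0))
            if use_time:
                cols.append(np.tile(t_c, U))
            Z = np.column_stack(cols)
            mu0 = (E[:, d, :] * np.exp(alpha[d])).ravel()
            info = Z.T @ (Z * mu0[:, None]) + 1e-8 * np.eye(nprop0)
            prop_chol.append(np.linalg.cholesky(np.linalg.inv(info)))

        steps = {
            **{f"abg_{d}": _AdaptiveScale(2.0 / math.sqrt(nprop0)) for d in range(D)},
            "delta": _AdaptiveScale(0.05),
            "delta_shear": _AdaptiveScale(0.1),
            "s2_phi": _AdaptiveScale(0.3), "rho_phi": _AdaptiveScale(0.3),
            "s2_psi": _AdaptiveScale(0.3), "rho_psi": _AdaptiveScale(0.3),
            "scale_phi": _AdaptiveScale(0.2), "scale_psi": _AdaptiveScale(0.2),
            **{f"tr_phi_{v}": _AdaptiveScale(0.1) for v in range(p + 1)},
            **{f"tr_psi_{d}_{v}": _AdaptiveScale(0.1)
               for d in range(D) for v in range(p + 1)},
        }
        ones_u = np.ones(U)

        keep = 0
        for it in range(spec.n_iter):
            in_burn = it < spec.burn_in
            if not in_burn:
                for a in steps.values():
                    a.frozen = True

            # (a) impute censored counts from the truncated Poisson
            if C:
                cmat = c_field()
                mu_cells = E[ci, cd, ct] * np.exp(cmat[ci, cd] + g[cd, ct])
                y_new = sample_truncated_poisson(mu_cells, c_lo, c_hi, rng)
                y[ci, cd, ct] = y_new
                S_ud = y.sum(axis=2)
                Yt_dt = y.sum(axis=0)

            # (b) per-disease fixed effects + time slope
            for d in range(D):
                ad = steps[f"abg_{d}"]
                cur = ll_disease(d, alpha[d], beta[d], gamma[d])
                z = ad.scale * (prop_chol[d] @ rng.standard_normal(nprop0))
                a_p = alpha[d] + z[0]
                b_p = beta[d] + z[1:1 + p]
                g_p = gamma[d] + (z[-1] if use_time else 0.0)
                prop = ll_disease(d, a_p, b_p, g_p)
                dprior = (-(a_p**2 - alpha[d]**2)
                          - np.sum(b_p**2 - beta[d]**2)
                          - (g_p**2 - gamma[d]**2)) / (2 * spec.prior_sd**2)
                if math.log(rng.uniform()) < prop - cur + dprior:
                    alpha[d], beta[d], gamma[d] = a_p, b_p, g_p
                    if use_time:
                        g[d] = gamma[d] * t_c
                        Eg[:, d] = E[:, d, :] @ np.exp(g[d])
                    ad.update(True)
                else:
                    ad.update(False)

            base_c = alpha[None, :] + (X @ beta.T if p else 0.0)

            # (c) shared field by elliptical slice sampling (repeated: the
            # field's shape is the slow direction for the loadings)
            if sample_phi:
                def ll_phi(ph):
                    return ll_c(base_c + delta[None, :] * ph[:, None] + psi)
                for _ in range(3):
                    nu = math.sqrt(sigma2_phi) * (gp_phi.L @ rng.standard_normal(U))
                    logy = ll_phi(phi) + math.log(rng.uniform())
                    t_ang = rng.uniform(0, 2 * math.pi)
                    t_min, t_max = t_ang - 2 * math.pi, t_ang
                    while True:
                        cand = phi * math.cos(t_ang) + nu * math.sin(t_ang)
                        if ll_phi(cand) > logy:
                            phi = cand
                            break
                        if t_ang < 0:
                            t_min = t_ang
                        else:
                            t_max = t_ang
                        t_ang = rng.uniform(t_min, t_max)

            # (c') specific fields
            if use_psi:
                shared_part = base_c + delta[None, :] * phi[:, None]
                for d in range(D):
                    other = shared_part[:, d]

                    def ll_psi(col, d=d, other=other):
                        cm = other + col
                        return float(S_ud[:, d] @ cm - np.exp(cm) @ Eg[:, d])
                    nu = math.sqrt(sigma2_psi) * (gp_psi.L @ rng.standard_normal(U))
                    col = psi[:, d]
                    logy = ll_psi(col) + math.log(rng.uniform())
                    t_ang = rng.uniform(0, 2 * math.pi)
                    t_min, t_max = t_ang - 2 * math.pi, t_ang
                    while True:
                        cand = col * math.cos(t_ang) + nu * math.sin(t_ang)
                        if ll_psi(cand) > logy:
                            psi[:, d] = cand
                            break
                        if t_ang < 0:
                            t_min = t_ang
                        else:
                            t_max = t_ang
                        t_ang = rng.uniform(t_min, t_max)

            # (c'') likelihood-invariant translation moves along the
            # confounded directions: shift the component of a field lying in
            # span{1, x_j} into the intercept / covariate coefficient.  Only
            # the priors enter the acceptance ratio, so these moves decouple
            # the fields from the fixed effects at almost no cost.
            if sample_phi:
                for v_idx in range(p + 1):
                    ad = steps[f"tr_phi_{v_idx}"]
                    v = ones_u if v_idx == 0 else X[:, v_idx - 1]
                    c = rng.standard_normal() * ad.scale
                    phi_p = phi - c * v
                    dlp = gp_phi.quad_shift(phi, v_idx, v, c, sigma2_phi)
                    if v_idx == 0:
                        par_new = alpha + delta * c
                        dlp += np.sum(alpha**2 - par_new**2) / (2 * spec.prior_sd**2)
                    else:
                        par_new = beta[:, v_idx - 1] + delta * c
                        dlp += np.sum(beta[:, v_idx - 1]**2 - par_new**2) / (2 * spec.prior_sd**2)
                    if math.log(rng.uniform()) < dlp:
                        phi = phi_p
                        if v_idx == 0:
                            alpha = par_new
                        else:
                            beta[:, v_idx - 1] = par_new
                        ad.update(True)
                    else:
                        ad.update(False)

            if use_psi:
                for d in range(D):
                    for v_idx in range(p + 1):
                        ad = steps[f"tr_psi_{d}_{v_idx}"]
                        v = ones_u if v_idx == 0 else X[:, v_idx - 1]
                        c = rng.standard_normal() * ad.scale
                        col_p = psi[:, d] - c * v
                        dlp = gp_psi.quad_shift(psi[:, d], v_idx, v, c, sigma2_psi)
                        if v_idx == 0:
                            old, new = alpha[d], alpha[d] + c
                        else:
                            old, new = beta[d, v_idx - 1], beta[d, v_idx - 1] + c
                        dlp += (old**2 - new**2) / (2 * spec.prior_sd**2)
                        if math.log(rng.uniform()) < dlp:
                            psi[:, d] = col_p
                            if v_idx == 0:
                                alpha[d] = new
                            else:
                                beta[d, v_idx - 1] = new
                            ad.update(True)
                        else:
                            ad.update(False)

            base_c = alpha[None, :] + (X @ beta.T if p else 0.0)

            # (d) shared-component loadings on the sum-zero log subspace.
            # Repeated several times per sweep: the blocks are cheap and the
            # loadings are the slowest-mixing parameters.
            for _ in range(5 if sample_delta else 0):
                ad = steps["delta"]
                u_prop = u_delta + rng.standard_normal(D - 1) * ad.scale
                delta_prop = np.exp(B_delta @ u_prop)
                cur = ll_c(base_c + delta[None, :] * phi[:, None] + psi)
                prop = ll_c(base_c + delta_prop[None, :] * phi[:, None] + psi)
                dprior = -(np.sum(u_prop**2) - np.sum(u_delta**2)) / (2 * spec.delta_log_sd**2)
                if math.log(rng.uniform()) < prop - cur + dprior:
                    u_delta, delta = u_prop, delta_prop
                    ad.update(True)
                else:
                    ad.update(False)

                # shear companion: change the loadings and absorb the
                # difference into the specific fields (psi_d' = psi_d +
                # (delta_d - delta_d') phi), leaving the likelihood
                # untouched.  Breaks the delta-psi confounding that plain
                # updates cannot cross.
                if use_psi:
                    ad = steps["delta_shear"]
                    u_prop = u_delta + rng.standard_normal(D - 1) * ad.scale
                    delta_prop = np.exp(B_delta @ u_prop)
                    psi_prop = psi + (delta - delta_prop)[None, :] * phi[:, None]
                    dlp = (gp_psi.logpdf(psi_prop, sigma2_psi)
                           - gp_psi.logpdf(psi, sigma2_psi)
                           - (np.sum(u_prop**2) - np.sum(u_delta**2))
                           / (2 * spec.delta_log_sd**2))
                    if math.log(rng.uniform()) < dlp:
                        u_delta, delta, psi = u_prop, delta_prop, psi_prop
                        ad.update(True)
                    else:
                        ad.update(False)

            # (e) covariance parameters, log-scale Metropolis
            if sample_phi and not phi_var_fixed:
                ad = steps["s2_phi"]
                s2p = sigma2_phi * math.exp(rng.standard_normal() * ad.scale)
                cur = gp_phi.logpdf(phi, sigma2_phi) \
                    - sigma2_phi**2 / (2 * spec.sigma2_half_normal_scale**2) \
                    + math.log(sigma2_phi)
                prop = gp_phi.logpdf(phi, s2p) \
                    - s2p**2 / (2 * spec.sigma2_half_normal_scale**2) + math.log(s2p)
                if math.log(rng.uniform()) < prop - cur:
                    sigma2_phi = s2p
                    ad.update(True)
                else:
                    ad.update(False)

                # funnel-breaking joint rescale of (phi, sigma2_phi)
                ad = steps["scale_phi"]
                s = math.exp(rng.standard_normal() * ad.scale)
                phi_p = phi * s
                s2p = sigma2_phi * s * s
                cur_ll = ll_c(base_c + delta[None, :] * phi[:, None] + psi)
                prop_ll = ll_c(base_c + delta[None, :] * phi_p[:, None] + psi)
                dprior = (-(s2p**2 - sigma2_phi**2) / (2 * spec.sigma2_half_normal_scale**2)
                          + math.log(s2p) - math.log(sigma2_phi))
                if math.log(rng.uniform()) < prop_ll - cur_ll + dprior:
                    phi, sigma2_phi = phi_p, s2p
                    ad.update(True)
                else:
                    ad.update(False)

            if sample_phi and spec.rho_phi_fixed is None:
                ad = steps["rho_phi"]
                rho_p = rho_phi * math.exp(rng.standard_normal() * ad.scale)
                if rho_lo <= rho_p <= rho_hi:
                    gp_p = _GP(dist, rho_p, 0.0, V_dir)
                    cur = gp_phi.logpdf(phi, sigma2_phi) + math.log(rho_phi)
                    prop = gp_p.logpdf(phi, sigma2_phi) + math.log(rho_p)
                    if math.log(rng.uniform()) < prop - cur:
                        rho_phi, gp_phi = rho_p, gp_p
                        ad.update(True)
                    else:
                        ad.update(False)
                else:
                    ad.update(False)

            if use_psi and not psi_var_fixed:
                ad = steps["s2_psi"]
                s2p = sigma2_psi * math.exp(rng.standard_normal() * ad.scale)
                cur = gp_psi.logpdf(psi, sigma2_psi) \
                    - sigma2_psi**2 / (2 * spec.sigma2_half_normal_scale**2) \
                    + math.log(sigma2_psi)
                prop = gp_psi.logpdf(psi, s2p) \
                    - s2p**2 / (2 * spec.sigma2_half_normal_scale**2) + math.log(s2p)
                if math.log(rng.uniform()) < prop - cur:
                    sigma2_psi = s2p
                    ad.update(True)
                else:
                    ad.update(False)

                ad = steps["scale_psi"]
                s = math.exp(rng.standard_normal() * ad.scale)
                psi_p = psi * s
                s2p = sigma2_psi * s * s
                cur_ll = ll_c(base_c + delta[None, :] * phi[:, None] + psi)
                prop_ll = ll_c(base_c + delta[None, :] * phi[:, None] + psi_p)
                dprior = (-(s2p**2 - sigma2_psi**2) / (2 * spec.sigma2_half_normal_scale**2)
                          + math.log(s2p) - math.log(sigma2_psi))
                if math.log(rng.uniform()) < prop_ll - cur_ll + dprior:
                    psi, sigma2_psi = psi_p, s2p
                    ad.update(True)
                else:
                    ad.update(False)

            if use_psi and spec.rho_psi_fixed is None:
                ad = steps["rho_psi"]
                rho_p = rho_psi * math.exp(rng.standard_normal() * ad.scale)
                if rho_lo <= rho_p <= rho_hi:
                    gp_p = _GP(dist, rho_p, spec.psi_nugget, V_dir)
                    cur = gp_psi.logpdf(psi, sigma2_psi) + math.log(rho_psi)
                    prop = gp_p.logpdf(psi, sigma2_psi) + math.log(rho_p)
                    if math.log(rng.uniform()) < prop - cur:
                        rho_psi, gp_psi = rho_p, gp_p
                        ad.update(True)
                    else:
                        ad.update(False)
                else:
                    ad.update(False)

            if not in_burn and (it - spec.burn_in) % spec.thinning == 0 and keep < n_keep:
                s = chain_id * n_keep + keep
                store["alpha"][s] = alpha
                store["beta"][s] = beta
                store["gamma"][s] = gamma
                store["delta"][s] = delta
                store["phi"][s] = phi
                store["psi"][s] = psi
                store["sigma2_phi"][s] = sigma2_phi if sample_phi else 0.0
                store["rho_phi"][s] = rho_phi
                store["sigma2_psi"][s] = sigma2_psi if use_psi else 0.0
                store["rho_psi"][s] = rho_psi
                if C:
                    store["imputed"][s] = y[ci, cd, ct]
                store["chain"][s] = chain_id
                keep += 1

        for name, a in steps.items():
            acceptance[f"{name}_chain{chain_id}"] = a.rate

    return PosteriorSamples(
        units=list(panel.units), diseases=list(panel.diseases),
        periods=list(panel.periods), covariate_names=names,
        alpha=store["alpha"], beta=store["beta"], gamma=store["gamma"],
        delta=store["delta"], phi=store["phi"], psi=store["psi"],
        sigma2_phi=store["sigma2_phi"], rho_phi=store["rho_phi"],
        sigma2_psi=store["sigma2_psi"], rho_psi=store["rho_psi"],
        imputed=store["imputed"], cens_index=cens if C else np.empty((0, 3), int),
        chain=store["chain"], acceptance=acceptance,
        X=X, x_center=x_center, x_scale=x_scale, t_centered=t_c,
    )


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


@dataclass
class RiskSurface:
    """Per-unit, per-disease posterior relative-risk summary."""

    units: list[str]
    diseases: list[str]
    mean: np.ndarray           # (U, D) posterior mean of period-averaged theta
    sd: np.ndarray             # (U, D)
    cumulative: np.ndarray     # (U,) P(at least one diagnosis over the window)
    n_diseases: np.ndarray     # (U,) diseases with any case in the unit

    def frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product([self.units, self.diseases],
                                         names=["unit_id", "disease"])
        return pd.DataFrame({"risk_mean": self.mean.ravel(),
                             "risk_sd": self.sd.ravel()}, index=idx).reset_index()


def summarize_risk(samples: PosteriorSamples, panel: CountPanel) -> RiskSurface:
    """Posterior mean/sd of period-averaged relative risk, plus cumulative
    risk and the disease-count layer."""
    S = samples.n_draws
    U, D, T = panel.shape
    m1 = np.zeros((U, D))
    m2 = np.zeros((U, D))
    cum = np.zeros(U)
    pop = np.maximum(panel.population, 1e-12)
    for s in range(S):
        th = np.exp(samples.log_theta(s))
        bar = th.mean(axis=2)
        m1 += bar
        m2 += bar * bar
        haz = (panel.expected * th).sum(axis=(1, 2)) / pop
        cum += 1.0 - np.exp(-haz)
    mean = m1 / S
    sd = np.sqrt(np.maximum(m2 / S - mean**2, 0.0))
    cum /= S

    lo, hi = panel.bounds()
    any_case = (lo >= 1).any(axis=2)  # observed>0 or interval lo>=1
    if samples.cens_index.shape[0]:
        miss = np.isinf(hi) & np.isnan(panel.value)
        if miss.any() and samples.imputed.size:
            imput_mean = samples.imputed.mean(axis=0)
            for k, (i, d, t) in enumerate(samples.cens_index):
                if miss[i, d, t] and imput_mean[k] > 0.5:
                    any_case[i, d] = True
    n_dis = any_case.sum(axis=1)
    return RiskSurface(list(panel.units), list(panel.diseases), mean, sd, cum, n_dis)


def cumulative_risk(samples: PosteriorSamples, geo: Geography, panel: CountPanel) -> np.ndarray:
    """Posterior mean probability of at least one diagnosis per person.

    Per draw, the per-person cumulative hazard in unit i is
    h_i = sum_{d,t} E_dit * theta_dit / pop_i and the risk is 1 - exp(-h_i).
    """
    if np.any(panel.population <= 0):
        raise ValueError("cumulative risk needs positive populations")
    S = samples.n_draws
    out = np.zeros(len(panel.units))
    for s in range(S):
        th = np.exp(samples.log_theta(s))
        haz = (panel.expected * th).sum(axis=(1, 2)) / panel.population
        out += 1.0 - np.exp(-haz)
    return out / S


def downscale_to_fine(
    samples: PosteriorSamples,
    geo: Geography,
    fine_covariates: pd.DataFrame,
    n_draws: int | None = 100,
    seed: int = 0,
) -> RiskSurface:
    """Predict relative risk at the fine level by GP conditional simulation.

    For each retained draw, the shared and specific fields at the fine
    centroids are drawn from their Gaussian conditional given the
    sector-level values (kriging mean plus conditional covariance); a fine
    unit whose centroid coincides with a sector centroid reproduces that
    sector's field value exactly.  Fine covariates are standardized with the
    centering used in the fit.
    """
    from scipy.linalg import cho_factor, cho_solve

    rng = np.random.default_rng(seed)
    fine = geo.level_frame("fine")
    fine_ids = fine["unit_id"].tolist()
    fxy = fine[["x", "y"]].to_numpy(float)
    sec_order = {u: i for i, u in enumerate(geo.unit_ids("sector"))}
    sxy = geo.centroids("sector")[[sec_order[u] for u in samples.units]]

    p = len(samples.covariate_names)
    if p:
        Xf_raw = fine_covariates[samples.covariate_names].to_numpy(float)
        Xf = (Xf_raw - samples.x_center) / samples.x_scale
    else:
        Xf = np.empty((len(fine_ids), 0))

    d_fs = cdist(fxy, sxy)
    d_ff = cdist(fxy, fxy)
    d_ss = cdist(sxy, sxy)
    coincident = d_fs.min(axis=1) < 1e-9
    match = d_fs.argmin(axis=1)

    S = samples.n_draws
    draw_ids = (np.arange(S) if n_draws is None or n_draws >= S
                else np.linspace(0, S - 1, n_draws).astype(int))
    U_f, D = len(fine_ids), len(samples.diseases)
    m1 = np.zeros((U_f, D))
    m2 = np.zeros((U_f, D))
    mean_exp_g = None

    def conditional_draw(field_s: np.ndarray, sigma2: float, rho: float,
                         n_cols: int) -> np.ndarray:
        """Columns drawn from the GP conditional at fine sites. field_s (U_s, n_cols)."""
        if sigma2 <= 0:
            return np.zeros((U_f, n_cols))
        R_ss = np.exp(-d_ss / rho) + 1e-9 * np.eye(len(sxy))
        R_fs = np.exp(-d_fs / rho)
        R_ff = np.exp(-d_ff / rho)
        fac = cho_factor(R_ss, lower=True)
        w = cho_solve(fac, field_s)           # (U_s, n_cols)
        mean = R_fs @ w
        Cv = sigma2 * (R_ff - R_fs @ cho_solve(fac, R_fs.T))
        Cv = (Cv + Cv.T) / 2 + 1e-9 * sigma2 * np.eye(U_f)
        L = np.linalg.cholesky(Cv)
        out = mean + L @ rng.standard_normal((U_f, n_cols))
        out[coincident] = field_s[match[coincident]]
        return out

    for s in draw_ids:
        phi_f = conditional_draw(samples.phi[s][:, None], samples.sigma2_phi[s],
                                 samples.rho_phi[s], 1)[:, 0]
        psi_f = conditional_draw(samples.psi[s], samples.sigma2_psi[s],
                                 samples.rho_psi[s], D)
        c = (samples.alpha[s][None, :] + (Xf @ samples.beta[s].T if p else 0.0)
             + samples.delta[s][None, :] * phi_f[:, None] + psi_f)
        gbar = np.exp(samples.gamma[s][:, None] * samples.t_centered[None, :]).mean(axis=1)
        th = np.exp(c) * gbar[None, :]
        m1 += th
        m2 += th * th
    n = len(draw_ids)
    mean = m1 / n
    sd = np.sqrt(np.maximum(m2 / n - mean**2, 0.0))
    return RiskSurface(fine_ids, list(samples.diseases), mean, sd,
                       np.full(U_f, np.nan), np.zeros(U_f, dtype=int))


# ---------------------------------------------------------------------------
# Mediation scan
# ---------------------------------------------------------------------------


def mediation_scan(
    panel: CountPanel,
    base_covariates: Sequence[str],
    mediators: Sequence[str],
    disease: str,
) -> pd.DataFrame:
    """Odds-ratio sensitivity of base covariates to candidate mediators.

    The outcome is binary presence (any case in a unit-period cell) for the
    given disease.  For each mediator, the logistic model is refit with the
    mediator added and the percent change in each base covariate's odds
    ratio is reported; changes above 10% are flagged.  Cells whose presence
    cannot be determined (missing counts) are dropped; perfect separation is
    flagged and the estimates omitted.
    """
    import statsmodels.api as sm

    d = panel.diseases.index(disease)
    lo, hi = panel.bounds()
    present = (lo[:, d, :] >= 1)
    known = ~(np.isnan(panel.value[:, d, :]) & np.isinf(hi[:, d, :]))
    U, _, T = panel.shape
    yv = present.ravel()[known.ravel()]
    cov = panel.covariates
    rows = np.repeat(np.arange(U), T)[known.ravel()]

    def fit(cols: list[str]):
        X = sm.add_constant(cov[cols].to_numpy(float)[rows], has_constant="add")
        try:
            res = sm.GLM(yv.astype(float), X, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception:
            return None
        if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 15):
            return None  # separation / divergence
        return dict(zip(cols, res.params[1:]))

    base = list(base_covariates)
    coefs0 = fit(base)
    records = []
    for m in mediators:
        coefs1 = fit(base + [m]) if coefs0 is not None else None
        for v in base:
            if coefs0 is None or coefs1 is None:
                records.append((m, v, np.nan, np.nan, np.nan, True, False))
                continue
            or0 = math.exp(coefs0[v])
            or1 = math.exp(coefs1[v])
            pct = 100.0 * (or1 - or0) / or0
            records.append((m, v, or0, or1, pct, False, abs(pct) > 10.0))
    return pd.DataFrame(records, columns=[
        "mediator", "variable", "or_without", "or_with", "pct_change",
        "separation", "flagged"])
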