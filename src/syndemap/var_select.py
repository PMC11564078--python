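"""Covariate screening via a censored lognormal accelerated-failure-time fit.

Counts are not survival times, but an AFT regression on the log-shifted
count log(y + 1) gives a fast deterministic likelihood that accommodates the
confidentiality intervals exactly: an observed count contributes the normal
density at log(y + 1), a censored interval [lo, hi] contributes the normal
probability of [log(lo + 1), log(hi + 1)].  Inference is made robust to the
repeated measures within an areal unit by a cluster sandwich variance.
Model search is forward-backward stepwise on AIC, pooled across diseases
with disease indicator main effects always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .geo_synth import CountPanel

__all__ = ["AFTFit", "SelectionTrace", "StepwiseConfig", "fit_aft_lognormal",
           "stepwise_select", "AFTConvergenceError"]

_LOG_SCALE_BOUNDS = (-8.0, 8.0)


class AFTConvergenceError(RuntimeError):
    """The AFT likelihood has no interior maximum (or optimisation failed)."""


@dataclass
class AFTFit:
    coefficients: np.ndarray     # intercept first, log-time scale
    scale: float                 # lognormal sd
    loglik: float
    aic: float
    robust_se: np.ndarray
    naive_se: np.ndarray
    n_obs: int
    n_censored: int
    names: list[str] = field(default_factory=list)


@dataclass
class SelectionTrace:
    steps: list[tuple]           # (step, action, variable, aic_before, aic_after)
    final_variables: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "action", "variable", "aic_before", "aic_after"])


def _prepare(y_lo: np.ndarray, y_hi: np.ndarray) -> tuple[np.ndarray, ...]:
    """Log-shifted response: points z, and censored log-bounds [zl, zu]."""
    obs = y_lo == y_hi
    z = np.log(y_lo + 1.0)
    zl = np.log(y_lo + 1.0)
    zu = np.where(np.isinf(y_hi), np.inf, np.log(y_hi + 1.0))
    return obs, z, zl, zu


def _nll_and_grad(theta, X, obs, z, zl, zu):
    k = X.shape[1]
    b, log_s = theta[:k], theta[k]
    s = np.exp(log_s)
    mu = X @ b
    nll = 0.0
    dmu = np.zeros(len(z))   # d loglik / d mu per observation
    dls = np.zeros(len(z))   # d loglik / d log s per observation

    r = (z[obs] - mu[obs]) / s
    nll -= np.sum(-0.5 * r * r - log_s - 0.5 * np.log(2 * np.pi))
    dmu[obs] = r / s
    dls[obs] = r * r - 1.0

    cen = ~obs
    if cen.any():
        a = (zl[cen] - mu[cen]) / s
        bb = np.where(np.isinf(zu[cen]), np.inf, (zu[cen] - mu[cen]) / s)
        P = norm.cdf(bb) - norm.cdf(a)
        P = np.maximum(P, 1e-300)
        pa = norm.pdf(a)
        pb = np.where(np.isinf(bb), 0.0, norm.pdf(bb))
        nll -= np.sum(np.log(P))
        dmu[cen] = -(pb - pa) / (s * P)
        bpb = np.where(np.isinf(bb), 0.0, bb * pb)
        dls[cen] = -(bpb - a * pa) / P

    grad = np.empty(k + 1)
    grad[:k] = -(X.T @ dmu)
    grad[k] = -np.sum(dls)
    return nll, grad, dmu, dls


def _scores(theta, X, obs, z, zl, zu) -> np.ndarray:
    """Per-observation score matrix (n x (k+1)) of the log-likelihood."""
    _, _, dmu, dls = _nll_and_grad(theta, X, obs, z, zl, zu)
    return np.column_stack([X * dmu[:, None], dls])


def fit_aft_lognormal(
    y_lo: np.ndarray,
    y_hi: np.ndarray,
    X: np.ndarray,
    clusters: np.ndarray,
    names: list[str] | None = None,
) -> AFTFit:
    """Maximum-likelihood lognormal AFT fit on log(y + 1).

    ``y_lo``/``y_hi`` are elementwise count bounds (equal where observed;
    ``hi`` may be +inf).  ``X`` must include the intercept column and be of
    full column rank.  ``clusters`` are areal-unit labels for the sandwich
    variance.
    """
    y_lo = np.asarray(y_lo, float)
    y_hi = np.asarray(y_hi, float)
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] != len(y_lo):
        raise ValueError("X must be (n, k)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    obs, z, zl, zu = _prepare(y_lo, y_hi)
    n, k = X.shape

    # start at OLS on the midpoint-filled log response: exact optimum when
    # nothing is censored, a good neighbourhood otherwise
    z0 = np.where(obs, z, np.log((y_lo + np.where(np.isinf(y_hi), y_lo, y_hi)) / 2 + 1))
    b0, *_ = np.linalg.lstsq(X, z0, rcond=None)
    resid = z0 - X @ b0
    s0 = max(np.sqrt(np.mean(resid**2)), 1e-3)
    theta0 = np.concatenate([b0, [np.log(s0)]])

    bounds = [(None, None)] * k + [_LOG_SCALE_BOUNDS]
    res = optimize.minimize(
        lambda th: _nll_and_grad(th, X, obs, z, zl, zu)[:2],
        theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.status != 0:
        raise AFTConvergenceError(f"AFT optimisation failed: {res.message}")
    log_s = res.x[k]
    if log_s <= _LOG_SCALE_BOUNDS[0] + 1e-6 or log_s >= _LOG_SCALE_BOUNDS[1] - 1e-6:
        raise AFTConvergenceError("scale at boundary: likelihood has no interior maximum")

    theta = res.x
    loglik = -float(res.fun)
    # observed information by central differences of the analytic gradient
    h = 1e-5
    A = np.zeros((k + 1, k + 1))
    for j in range(k + 1):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp = _nll_and_grad(tp, X, obs, z, zl, zu)[1]
        gm = _nll_and_grad(tm, X, obs, z, zl, zu)[1]
        A[:, j] = (gp - gm) / (2 * h)
    A = (A + A.T) / 2
    eig = np.linalg.eigvalsh(A)
    if eig[0] <= 1e-10 * max(1.0, eig[-1]):
        raise AFTConvergenceError(
            "flat likelihood direction (observed information singular); "
            "the censoring pattern does not identify the model")
    Ainv = np.linalg.pinv(A)
    naive_se = np.sqrt(np.maximum(np.diag(Ainv), 0.0))

    S = _scores(theta, X, obs, z, zl, zu)
    cl = pd.factorize(np.asarray(clusters))[0]
    G = np.zeros((cl.max() + 1, k + 1))
    np.add.at(G, cl, S)
    B = G.T @ G
    V = Ainv @ B @ Ainv
    robust_se = np.sqrt(np.maximum(np.diag(V), 0.0))

    n_par = k + 1
    return AFTFit(
        coefficients=theta[:k],
        scale=float(np.exp(log_s)),
        loglik=float(loglik),
        aic=float(2 * n_par - 2 * loglik),
        robust_se=robust_se[:k],
        naive_se=naive_se[:k],
        n_obs=n,
        n_censored=int((~obs).sum()),
        names=names or [f"b{j}" for j in range(k)],
    )


@dataclass
class StepwiseConfig:
    max_steps: int = 50
    #: "aic" for AIC descent; "pvalue" enters/drops on robust-Wald p-values
    criterion: str = "aic"
    p_enter: float = 0.05
    p_remove: float = 0.10


def _panel_long(panel: CountPanel, candidates: pd.DataFrame):
    """Pooled long response and always-included base design.

    Base design: intercept + disease indicators (reference = first disease).
    Candidate columns are unit-level values replicated over disease and
    period.
    """
    U, D, T = panel.shape
    lo, hi = panel.bounds()
    y_lo = lo.ravel()   # order (unit, disease, period)
    y_hi = hi.ravel()
    base_cols = ["intercept"] + [f"disease[{d}]" for d in panel.diseases[1:]]
    Xb = np.zeros((U * D * T, len(base_cols)))
    Xb[:, 0] = 1.0
    d_idx = np.tile(np.repeat(np.arange(D), T), U)
    for j in range(1, D):
        Xb[:, j] = (d_idx == j).astype(float)
    cand = candidates.to_numpy(float)
    Xc = np.repeat(cand, D * T, axis=0)
    clusters = np.repeat(np.arange(U), D * T)
    return y_lo, y_hi, Xb, base_cols, Xc, list(candidates.columns), clusters


def stepwise_select(
    panel: CountPanel,
    candidates: pd.DataFrame,
    config: StepwiseConfig | None = None,
) -> SelectionTrace:
    """Forward-backward stepwise covariate selection, pooled over diseases.

    All diseases are modelled together (disease indicators always included)
    so that the selected set reflects factors shared across diseases; this
    mirrors a screening step run once for the whole joint model rather than
    per disease.  Deterministic: candidates are tried in column order and
    ties break toward the earlier column.
    """
    cfg = config or StepwiseConfig()
    y_lo, y_hi, Xb, base_names, Xc, cand_names, clusters = _panel_long(panel, candidates)

    def fit_with(sel: list[int]) -> AFTFit:
        X = np.column_stack([Xb] + [Xc[:, [j]] for j in sel]) if sel else Xb
        nm = base_names + [cand_names[j] for j in sel]
        return fit_aft_lognormal(y_lo, y_hi, X, clusters, names=nm)

    if cfg.criterion == "pvalue":
        return _stepwise_pvalue(cfg, fit_with, Xc.shape[1], len(base_names), cand_names)
    if cfg.criterion != "aic":
        raise ValueError(f"unknown selection criterion {cfg.criterion!r}")

    selected: list[int] = []
    current = fit_with(selected)
    steps: list[tuple] = []
    for step in range(cfg.max_steps):
        best_action = None  # (new_aic, action, j, fit)
        for j in range(Xc.shape[1]):
            if j in selected:
                continue
            try:
                f = fit_with(selected + [j])
            except (AFTConvergenceError, ValueError):
                continue
            if f.aic < current.aic - 1e-9 and (best_action is None or f.aic < best_action[0] - 1e-9):
                best_action = (f.aic, "add", j, f)
        for j in selected:
            rest = [s for s in selected if s != j]
            try:
                f = fit_with(rest)
            except (AFTConvergenceError, ValueError):
                continue
            if f.aic < current.aic - 1e-9 and (best_action is None or f.aic < best_action[0] - 1e-9):
                best_action = (f.aic, "drop", j, f)
        if best_action is None:
            break
        aic_new, action, j, f = best_action
        steps.append((step, action, cand_names[j], current.aic, aic_new))
        if action == "add":
            selected = selected + [j]
        else:
            selected = [s for s in selected if s != j]
        current = f
    return SelectionTrace(steps, [cand_names[j] for j in selected])


def _stepwise_pvalue(cfg, fit_with, n_cand, n_base, cand_names) -> SelectionTrace:
    """Entry/stay selection on cluster-robust Wald p-values.

    Forward: add the candidate with the smallest p-value below ``p_enter``;
    backward: drop the selected variable with the largest p-value above
    ``p_remove``.  Ties break toward the earlier column.
    """
    from scipy.stats import norm as _norm

    def pvals(fit, sel):
        z = fit.coefficients[n_base:] / np.maximum(fit.robust_se[n_base:], 1e-300)
        return dict(zip(sel, 2 * _norm.sf(np.abs(z))))

    selected: list[int] = []
    steps: list[tuple] = []
    current = fit_with(selected)
    for step in range(cfg.max_steps):
        moved = False
        best = None  # (p, j, fit)
        for j in range(n_cand):
            if j in selected:
                continue
            try:
                f = fit_with(selected + [j])
            except (AFTConvergenceError, ValueError):
                continue
            p = pvals(f, selected + [j])[j]
            if p < cfg.p_enter and (best is None or p < best[0]):
                best = (p, j, f)
        if best is not None:
            p, j, f = best
            steps.append((step, "add", cand_names[j], current.aic, f.aic))
            selected, current, moved = selected + [j], f, True
        if selected:
            ps = pvals(current, selected)
            worst = max(selected, key=lambda j: (ps[j], -j))
            if ps[worst] > cfg.p_remove:
                f = fit_with([s for s in selected if s != worst])
                steps.append((step, "drop", cand_names[worst], current.aic, f.aic))
                selected = [s for s in selected if s != worst]
                current, moved = f, True
        if not moved:
            break
    return SelectionTrace(steps, [cand_names[j] for j in selected])
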