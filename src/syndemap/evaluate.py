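"""Model performance, information criteria, cross-validation and baseline.

Scores are computed from the retained posterior draws:

* per-disease mean error and mean squared error of the posterior-mean
  predicted counts against the observed counts;
* DIC (conditioning the deviance on the posterior-mean intensity) and WAIC
  (averaging over the posterior), with censored cells scored by their
  interval Poisson mass;
* 10%-hold-out cross-validation per disease with RMSE and the mean squared
  deviation ratio (MSDR) — squared errors scaled by the posterior
  predictive variance, so a calibrated model gives MSDR ~ 1;
* an independent-models baseline: one single-disease fit per disease with
  the shared component removed, so the comparison isolates the value of
  joint modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geo_synth import CountPanel, Geography
from .joint_model import (ModelSpec, PosteriorSamples, censored_poisson_loglik,
                          run_mcmc)

__all__ = ["ValidationReport", "performance", "information_criteria",
           "crossvalidate", "fit_independent_baseline", "predictive_moments"]


@dataclass
class ValidationReport:
    per_disease: pd.DataFrame      # me, mse per disease
    dic: float
    waic: float
    p_dic: float
    p_waic: float
    cv: pd.DataFrame | None = None
    baseline: pd.DataFrame | None = None


def predictive_moments(samples: PosteriorSamples, panel: CountPanel
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior predictive mean and variance of each cell count.

    mean = E[mu]; var = Var[mu] + E[mu]  (Poisson mixed over the posterior).
    """
    S = samples.n_draws
    m1 = np.zeros(panel.shape)
    m2 = np.zeros(panel.shape)
    for s in range(S):
        mu = samples.mu(s, panel)
        m1 += mu
        m2 += mu * mu
    m1 /= S
    m2 /= S
    return m1, np.maximum(m2 - m1**2, 0.0) + m1


def performance(samples: PosteriorSamples, panel: CountPanel,
                censored: str = "exclude") -> pd.DataFrame:
    """Per-disease mean error and mean squared error (observed - predicted).

    Censored cells are excluded by default; ``censored="midpoint"`` scores
    them against their interval midpoint.
    """
    pred, _ = predictive_moments(samples, panel)
    if censored == "exclude":
        obs = panel.value
        mask = ~np.isnan(obs)
    elif censored == "midpoint":
        obs = panel.midpoint_filled()
        mask = np.isfinite(obs)
    else:
        raise ValueError(f"unknown censored mode {censored!r}")
    rows = []
    for d, dis in enumerate(panel.diseases):
        m = mask[:, d, :]
        if not m.any():
            raise ValueError(f"no scoreable cells for disease {dis!r}")
        err = obs[:, d, :][m] - pred[:, d, :][m]
        rows.append((dis, float(err.mean()), float((err**2).mean()), int(m.sum())))
    return pd.DataFrame(rows, columns=["disease", "me", "mse", "n_cells"])


def _loglik_draws(samples: PosteriorSamples, panel: CountPanel) -> np.ndarray:
    """(S, n_cells) per-draw per-cell log-likelihood (interval mass where censored)."""
    lo, hi = panel.bounds()
    lo_f = lo.ravel()
    hi_f = hi.ravel()
    S = samples.n_draws
    out = np.empty((S, lo_f.size))
    for s in range(S):
        mu = np.maximum(samples.mu(s, panel).ravel(), 1e-300)
        out[s] = censored_poisson_loglik((lo_f, hi_f), mu)
    return out


def information_criteria(samples: PosteriorSamples, panel: CountPanel,
                         cell_loglik: np.ndarray | None = None
                         ) -> tuple[float, float, float, float]:
    """(DIC, WAIC, p_DIC, p_WAIC) from the retained draws.

    DIC = Dbar + p_D with p_D = Dbar - D(mu_bar); WAIC = -2 (lppd - p_WAIC)
    with p_WAIC the summed posterior variance of the per-cell log-likelihood.
    """
    if samples.n_draws < 10:
        raise ValueError("need at least 10 retained draws")
    ll = cell_loglik if cell_loglik is not None else _loglik_draws(samples, panel)
    S = ll.shape[0]

    dbar = float(-2.0 * ll.sum(axis=1).mean())
    # deviance at the posterior-mean intensity
    lo, hi = panel.bounds()
    mu_mean = np.zeros(panel.shape)
    for s in range(S):
        mu_mean += samples.mu(s, panel)
    mu_mean /= S
    d_hat = float(-2.0 * np.sum(censored_poisson_loglik(
        (lo.ravel(), hi.ravel()), np.maximum(mu_mean.ravel(), 1e-300))))
    p_d = dbar - d_hat
    dic = dbar + p_d

    lppd = float(np.sum(_logmeanexp(ll, axis=0)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    waic = -2.0 * (lppd - p_waic)
    return dic, waic, p_d, p_waic


def _logmeanexp(a: np.ndarray, axis: int) -> np.ndarray:
    from scipy.special import logsumexp
    return logsumexp(a, axis=axis) - np.log(a.shape[axis])


def crossvalidate(
    panel: CountPanel,
    selected_covariates,
    geo: Geography,
    spec: ModelSpec,
    frac: float = 0.10,
    seed: int = 0,
    unit_level: bool = False,
) -> pd.DataFrame:
    """Hold-out validation: RMSE and MSDR per disease.

    A fraction ``frac`` of the *observed* cells of each disease is held out
    uniformly at random (or whole units when ``unit_level``), the model is
    refit with those cells marked missing (they contribute no likelihood),
    and the held-out counts are scored against the posterior predictive mean
    and variance.  MSDR = mean((obs - pred)^2 / pred_var); ~1 for a
    calibrated model.
    """
    if frac <= 0 or frac >= 1:
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train = panel.copy()
    held: list[tuple[int, int, int]] = []
    U, D, T = panel.shape
    for d in range(D):
        obs_cells = np.argwhere(~np.isnan(panel.value[:, d, :]))
        if unit_level:
            units = np.unique(obs_cells[:, 0])
            n_hold = max(1, int(round(frac * len(units))))
            hold_units = rng.choice(units, size=n_hold, replace=False)
            chosen = obs_cells[np.isin(obs_cells[:, 0], hold_units)]
        else:
            n_hold = max(1, int(round(frac * len(obs_cells))))
            pick = rng.choice(len(obs_cells), size=n_hold, replace=False)
            chosen = obs_cells[pick]
        for i, t in chosen:
            train.value[i, d, t] = np.nan
            train.lo[i, d, t] = 0
            train.hi[i, d, t] = np.inf
            held.append((i, d, t))
    samples = run_mcmc(train, selected_covariates, geo, spec)
    pred, pvar = predictive_moments(samples, panel)
    rows = []
    held_arr = np.array(held)
    for d, dis in enumerate(panel.diseases):
        sel = held_arr[held_arr[:, 1] == d]
        obs = panel.value[sel[:, 0], d, sel[:, 2]]
        mu = pred[sel[:, 0], d, sel[:, 2]]
        v = np.maximum(pvar[sel[:, 0], d, sel[:, 2]], 1e-12)
        err = obs - mu
        rows.append((dis, float(np.sqrt(np.mean(err**2))),
                     float(np.mean(err**2 / v)), len(sel)))
    return pd.DataFrame(rows, columns=["disease", "rmse", "msdr", "n_held_out"])


def fit_independent_baseline(
    panel: CountPanel,
    selected_covariates,
    geo: Geography,
    spec: ModelSpec,
    censored: str = "midpoint",
    true_totals: np.ndarray | None = None,
) -> tuple[list[PosteriorSamples], pd.DataFrame]:
    """One single-disease spatial fit per disease (no shared component).

    Each disease keeps its own spatial field (the former specific field,
    with the loading pinned at 1) and the same covariates, so the only
    difference from the joint model is the absence of sharing.  Censored
    cells are replaced by their interval midpoint by default
    (``censored="augment"`` keeps the data augmentation, making likelihood
    comparisons with the joint fit like-for-like).  Reports the percent
    error of predicted vs actual total counts per disease, against
    ``true_totals`` when the simulation truth is known.
    """
    fits: list[PosteriorSamples] = []
    rows = []
    for d, dis in enumerate(panel.diseases):
        sub = panel.select_diseases([dis])
        if censored == "midpoint":
            filled = sub.midpoint_filled()
            keepmask = np.isfinite(filled)
            sub.value = np.where(keepmask, np.round(filled), np.nan)
            sub.lo = np.where(keepmask, np.nan, 0.0)
            sub.hi = np.where(keepmask, np.nan, np.inf)
        elif censored != "augment":
            raise ValueError(f"unknown censored mode {censored!r}")
        dspec = replace(spec, delta_fixed=True, include_specific_field=False,
                        seed=spec.seed + 101 * (d + 1))
        fit = run_mcmc(sub, selected_covariates, geo, dspec)
        fits.append(fit)
        pred = predictive_moments(fit, sub)[0]
        total_pred = float(pred.sum())
        if true_totals is not None:
            total_obs = float(true_totals[d])
        else:
            total_obs = float(np.nansum(panel.midpoint_filled()[:, d, :]))
        pct = 100.0 * (total_pred - total_obs) / max(total_obs, 1e-12)
        rows.append((dis, total_pred, total_obs, pct))
    table = pd.DataFrame(rows, columns=[
        "disease", "predicted_total", "actual_total", "pct_error"])
    return fits, table
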