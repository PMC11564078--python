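"""Crude and age-specific incidence rates with Poisson-approximation errors.

Rates are cases per person per (6-month) period at the panel's areal level.
The standard error of a rate y/pop is sqrt(y)/pop, the usual Poisson
approximation for registry counts.  Interval-censored cells contribute a
configurable point surrogate (midpoint by default) and are flagged so that
downstream summaries can treat them with caution.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .geo_synth import CountPanel, Geography

__all__ = ["incidence_rates", "rate_ratio_by_age"]


def _point_surrogate(panel: CountPanel, convention: str) -> np.ndarray:
    lo, hi = panel.bounds()
    if convention == "midpoint":
        pt = np.where(np.isinf(hi), lo, (lo + hi) / 2.0)
    elif convention == "lo":
        pt = lo
    elif convention == "hi":
        pt = np.where(np.isinf(hi), lo, hi)
    else:
        raise ValueError(f"unknown interval convention {convention!r}")
    return np.where(np.isnan(panel.value), pt, panel.value)


def incidence_rates(
    panel: CountPanel,
    geo: Geography,
    age_band: Literal["all", "under50", "over50"] = "all",
    interval_convention: str = "midpoint",
) -> pd.DataFrame:
    """Per (unit, disease, period) incidence rates.

    ``panel`` must already be the band-specific panel when ``age_band`` is a
    band (its counts are that band's counts); ``age_band`` selects which
    population denominator to use and labels the rows.  Censored cells use
    the interval surrogate and are flagged in ``imputed``.

    Returns a long table with columns unit_id, disease, period, age_band,
    n_cases, population, rate, se, imputed.
    """
    pop = geo.population(panel.level, age_band)
    order = {u: i for i, u in enumerate(geo.unit_ids(panel.level))}
    pop = np.array([pop[order[u]] for u in panel.units])
    y = _point_surrogate(panel, interval_convention)
    if np.any((pop == 0) & (y.sum(axis=(1, 2)) > 0)):
        bad = [u for i, u in enumerate(panel.units) if pop[i] == 0 and y[i].sum() > 0]
        raise ValueError(f"zero population with nonzero counts: {bad[:5]}")
    imputed = panel.is_censored
    U, D, T = panel.shape
    idx = pd.MultiIndex.from_product(
        [panel.units, panel.diseases, panel.periods],
        names=["unit_id", "disease", "period"])
    pop3 = np.broadcast_to(pop[:, None, None], (U, D, T))
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(pop3 > 0, y / pop3, 0.0)
        se = np.where(pop3 > 0, np.sqrt(y) / pop3, 0.0)
    out = pd.DataFrame({
        "age_band": age_band,
        "n_cases": y.ravel(),
        "population": pop3.ravel(),
        "rate": rate.ravel(),
        "se": se.ravel(),
        "imputed": imputed.ravel(),
    }, index=idx).reset_index()
    return out


def rate_ratio_by_age(table: pd.DataFrame) -> pd.DataFrame:
    """Over-50 / under-50 incidence rate ratio per disease.

    ``table`` is the concatenation of the two band-specific outputs of
    :func:`incidence_rates`.  Rates are pooled per disease and band (total
    cases over total person-periods) before taking the ratio; the standard
    error of the log ratio is the delta-method 1/y_over + 1/y_under.  Rows
    with a zero under-50 rate have an undefined ratio and are flagged.
    """
    bands = set(table["age_band"])
    if not {"under50", "over50"} <= bands:
        raise ValueError("table must contain both age bands")
    agg = (table.groupby(["disease", "age_band"])
           .agg(cases=("n_cases", "sum"), persons=("population", "sum"))
           .reset_index())
    agg["rate"] = np.where(agg["persons"] > 0, agg["cases"] / agg["persons"], 0.0)
    wide = agg.pivot(index="disease", columns="age_band", values=["rate", "cases"])
    r_o = wide[("rate", "over50")]
    r_u = wide[("rate", "under50")]
    y_o = wide[("cases", "over50")]
    y_u = wide[("cases", "under50")]
    undefined = r_u == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(undefined, np.nan, r_o / r_u)
        se_log = np.sqrt(np.where((y_o > 0) & (y_u > 0), 1.0 / y_o + 1.0 / y_u, np.nan))
        se = ratio * se_log  # delta method on the ratio scale
    return pd.DataFrame({
        "disease": wide.index,
        "rate_over50": r_o.to_numpy(),
        "rate_under50": r_u.to_numpy(),
        "ratio": ratio,
        "se": se,
        "undefined": undefined.to_numpy(),
    }).reset_index(drop=True)
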