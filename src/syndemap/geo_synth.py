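"""Synthetic nested geographies and multi-disease count panels.

Generates the data structures the joint spatial analysis operates on: a
three-level nested areal geography (fine units within sectors within
districts), unit-level covariates, latent shared/specific Gaussian spatial
fields, Poisson count panels, and the confidentiality censoring that replaces
small counts by an interval.

The generative model for relative risk is the shared-component form

    log theta_dit = alpha_d + x_i' beta_d + delta_d * phi_i + psi_di
                    + gamma_d * (t - t_bar)

with ``phi`` a zero-mean Gaussian process shared across diseases (exponential
covariance ``sigma2 * exp(-h / rho)`` over planar centroids, distances in km),
``psi_d`` disease-specific fields, and the loadings ``delta_d`` normalised so
their product is 1 (log-deltas sum to zero) for identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BANDS",
    "CensoredCount",
    "Geography",
    "CountPanel",
    "TruthConfig",
    "SimulationTruth",
    "make_geography",
    "simulate_panel",
    "simulate_age_split",
    "apply_confidentiality_censoring",
    "aggregate_to_parent",
    "internal_standardised_expected",
    "exponential_covariance",
    "panel_to_csv",
    "panel_from_csv",
    "geography_to_csv",
    "geography_from_csv",
    "geography_polygons_geojson",
]

AGE_BANDS = ("under50", "over50")

LEVELS = ("fine", "sector", "district")

#: token used in CSV files for an interval-censored small count, e.g. "<=5"
CENSOR_TOKEN_FMT = "<={hi}"

#: sentinel upper bound for "missing" cells (count unknown, no upper bound)
UNBOUNDED = np.inf


# ---------------------------------------------------------------------------
# Censored counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CensoredCount:
    """An observed count or an integer interval [lo, hi].

    ``status`` is one of ``"observed"``, ``"interval"`` or ``"missing"``.
    Missing cells (used for cross-validation hold-outs) carry no information:
    the count is only known to be a non-negative integer.
    """

    status: str
    value: int | None = None
    lo: int | None = None
    hi: float | None = None

    def __post_init__(self):
        if self.status == "observed":
            if self.value is None or self.value < 0:
                raise ValueError("observed count must be a non-negative integer")
        elif self.status == "interval":
            if self.lo is None or self.hi is None or not (1 <= self.lo <= self.hi):
                raise ValueError("interval must satisfy 1 <= lo <= hi")
        elif self.status == "missing":
            pass
        else:
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def is_censored(self) -> bool:
        return self.status != "observed"

    def bounds(self) -> tuple[int, float]:
        """Integer bounds [lo, hi] containing the true count."""
        if self.status == "observed":
            return int(self.value), int(self.value)
        if self.status == "interval":
            return int(self.lo), int(self.hi)
        return 0, UNBOUNDED


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


@dataclass
class Geography:
    """Three-level nested areal geography.

    ``units`` has one row per unit at every level with columns
    ``unit_id, level, parent_id, x, y, pop_under50, pop_over50``.
    Coordinates are planar km.  Child populations sum to the parent's.
    """

    units: pd.DataFrame

    def __post_init__(self):
        required = {"unit_id", "level", "parent_id", "x", "y", "pop_under50", "pop_over50"}
        missing = required - set(self.units.columns)
        if missing:
            raise ValueError(f"geography missing columns: {sorted(missing)}")
        self.units = self.units.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.units
        if not set(df["level"]).issubset(LEVELS):
            raise ValueError("unknown geography level")
        if df["unit_id"].duplicated().any():
            raise ValueError("duplicate unit ids")
        if (df[["pop_under50", "pop_over50"]] < 0).any().any():
            raise ValueError("negative population")
        by_id = df.set_index("unit_id")
        for child_level, parent_level in (("fine", "sector"), ("sector", "district")):
            children = df[df["level"] == child_level]
            if children.empty:
                continue
            parents = set(df.loc[df["level"] == parent_level, "unit_id"])
            bad = set(children["parent_id"]) - parents
            if bad:
                raise ValueError(f"{child_level} units with unknown parent: {sorted(bad)[:5]}")
            # child populations must sum to the parent's
            sums = children.groupby("parent_id")[["pop_under50", "pop_over50"]].sum()
            for pid, row in sums.iterrows():
                prow = by_id.loc[pid]
                if not (
                    np.isclose(row["pop_under50"], prow["pop_under50"], atol=1e-9)
                    and np.isclose(row["pop_over50"], prow["pop_over50"], atol=1e-9)
                ):
                    raise ValueError(f"population of children of {pid} does not sum to parent")
        # centroids distinct within each level
        for level in LEVELS:
            sub = df[df["level"] == level]
            if len(sub) and sub.duplicated(subset=["x", "y"]).any():
                raise ValueError(f"duplicate centroids at level {level}")

    def level_frame(self, level: str) -> pd.DataFrame:
        return self.units[self.units["level"] == level].reset_index(drop=True)

    def unit_ids(self, level: str) -> list[str]:
        return self.level_frame(level)["unit_id"].tolist()

    def centroids(self, level: str) -> np.ndarray:
        return self.level_frame(level)[["x", "y"]].to_numpy(float)

    def population(self, level: str, band: str = "all") -> np.ndarray:
        sub = self.level_frame(level)
        if band == "all":
            return (sub["pop_under50"] + sub["pop_over50"]).to_numpy(float)
        return sub[f"pop_{band}"].to_numpy(float)

    def parent_map(self, level: str) -> dict[str, str]:
        sub = self.level_frame(level)
        return dict(zip(sub["unit_id"], sub["parent_id"]))


def make_geography(n_fine: int, n_sectors: int, n_districts: int, seed: int) -> Geography:
    """Random nested geography with planar-km centroids in a 100x100 window.

    Sector centroids are a random subset of the fine centroids and district
    centroids a subset of the sector centroids, so nesting by nearest
    centroid always gives every parent at least one child (itself).
    Populations per fine unit are log-normal (median ~1500 residents, the
    LSOA scale) and split between the under-50 and over-50 bands.
    """
    if not (n_fine >= n_sectors >= n_districts >= 1):
        raise ValueError(
            f"hierarchy sizes must satisfy n_fine >= n_sectors >= n_districts >= 1, "
            f"got ({n_fine}, {n_sectors}, {n_districts})"
        )
    rng = np.random.default_rng(seed)
    window = 100.0
    fine_xy = rng.uniform(0, window, size=(n_fine, 2))
    sector_idx = rng.choice(n_fine, size=n_sectors, replace=False)
    sector_xy = fine_xy[sector_idx]
    district_idx = rng.choice(n_sectors, size=n_districts, replace=False)
    district_xy = sector_xy[district_idx]

    def nearest(points: np.ndarray, refs: np.ndarray) -> np.ndarray:
        d2 = ((points[:, None, :] - refs[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    fine_parent = nearest(fine_xy, sector_xy)
    sector_parent = nearest(sector_xy, district_xy)

    pop = rng.lognormal(mean=np.log(1500.0), sigma=0.35, size=n_fine)
    frac_under = rng.beta(20, 16, size=n_fine)  # ~55% under 50, UK-ish
    pop_u = pop * frac_under
    pop_o = pop * (1 - frac_under)

    fine_ids = [f"F{i:04d}" for i in range(n_fine)]
    sector_ids = [f"S{i:03d}" for i in range(n_sectors)]
    district_ids = [f"D{i:02d}" for i in range(n_districts)]

    rows = []
    for i in range(n_fine):
        rows.append((fine_ids[i], "fine", sector_ids[fine_parent[i]],
                     fine_xy[i, 0], fine_xy[i, 1], pop_u[i], pop_o[i]))
    sec_u = np.zeros(n_sectors)
    sec_o = np.zeros(n_sectors)
    np.add.at(sec_u, fine_parent, pop_u)
    np.add.at(sec_o, fine_parent, pop_o)
    for j in range(n_sectors):
        rows.append((sector_ids[j], "sector", district_ids[sector_parent[j]],
                     sector_xy[j, 0], sector_xy[j, 1], sec_u[j], sec_o[j]))
    dis_u = np.zeros(n_districts)
    dis_o = np.zeros(n_districts)
    np.add.at(dis_u, sector_parent, sec_u)
    np.add.at(dis_o, sector_parent, sec_o)
    for k in range(n_districts):
        rows.append((district_ids[k], "district", "",
                     district_xy[k, 0], district_xy[k, 1], dis_u[k], dis_o[k]))

    units = pd.DataFrame(
        rows, columns=["unit_id", "level", "parent_id", "x", "y", "pop_under50", "pop_over50"]
    )
    return Geography(units)


# ---------------------------------------------------------------------------
# Count panels
# ---------------------------------------------------------------------------


@dataclass
class CountPanel:
    """(unit x disease x period) panel of possibly censored counts.

    Internally counts are stored as three aligned arrays: ``value`` (float,
    NaN where censored/missing) and ``lo``/``hi`` bounds (NaN where
    observed; ``hi`` may be +inf for missing cells).  ``expected`` is the
    Poisson offset E, ``population`` the per-unit person counts, and
    ``covariates`` a standardized (unit x covariate) frame.
    """

    units: list[str]
    diseases: list[str]
    periods: list[int]
    value: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    expected: np.ndarray
    population: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    level: str = "sector"

    def __post_init__(self):
        shape = (len(self.units), len(self.diseases), len(self.periods))
        for name in ("value", "lo", "hi", "expected"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        self.population = np.asarray(self.population, float)
        if self.population.shape != (len(self.units),):
            raise ValueError("population must be per-unit")
        if np.any(self.expected[self.population > 0] <= 0):
            raise ValueError("expected counts must be positive where population > 0")
        if len(self.covariates) and len(self.covariates) != len(self.units):
            raise ValueError("covariates must have one row per unit")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.units), len(self.diseases), len(self.periods))

    @property
    def is_censored(self) -> np.ndarray:
        return np.isnan(self.value)

    @property
    def n_censored(self) -> int:
        return int(self.is_censored.sum())

    def cell(self, i: int, d: int, t: int) -> CensoredCount:
        if np.isnan(self.value[i, d, t]):
            hi = self.hi[i, d, t]
            if np.isinf(hi):
                return CensoredCount("missing")
            return CensoredCount("interval", lo=int(self.lo[i, d, t]), hi=int(hi))
        return CensoredCount("observed", value=int(self.value[i, d, t]))

    def set_cell(self, i: int, d: int, t: int, c: CensoredCount) -> None:
        if c.status == "observed":
            self.value[i, d, t] = c.value
            self.lo[i, d, t] = np.nan
            self.hi[i, d, t] = np.nan
        else:
            lo, hi = c.bounds()
            self.value[i, d, t] = np.nan
            self.lo[i, d, t] = lo
            self.hi[i, d, t] = hi

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Elementwise integer bounds [lo, hi] on the true counts."""
        lo = np.where(np.isnan(self.value), self.lo, self.value)
        hi = np.where(np.isnan(self.value), self.hi, self.value)
        return lo, hi

    def midpoint_filled(self) -> np.ndarray:
        """Counts with censored cells replaced by their interval midpoint."""
        lo, hi = self.bounds()
        mid = np.where(np.isinf(hi), lo, (lo + hi) / 2.0)
        return np.where(np.isnan(self.value), mid, self.value)

    def copy(self) -> "CountPanel":
        return CountPanel(
            list(self.units), list(self.diseases), list(self.periods),
            self.value.copy(), self.lo.copy(), self.hi.copy(),
            self.expected.copy(), self.population.copy(),
            self.covariates.copy(), self.level,
        )

    def select_diseases(self, names: Sequence[str]) -> "CountPanel":
        idx = [self.diseases.index(n) for n in names]
        return CountPanel(
            list(self.units), list(names), list(self.periods),
            self.value[:, idx, :].copy(), self.lo[:, idx, :].copy(),
            self.hi[:, idx, :].copy(), self.expected[:, idx, :].copy(),
            self.population.copy(), self.covariates.copy(), self.level,
        )


def exponential_covariance(coords: np.ndarray, sigma2: float, rho: float,
                           nugget: float = 0.0) -> np.ndarray:
    """sigma2 * exp(-h / rho) over pairwise distances h (km), plus a nugget."""
    from scipy.spatial.distance import cdist

    h = cdist(coords, coords)
    k = sigma2 * np.exp(-h / rho)
    if nugget:
        k = k + nugget * np.eye(len(coords))
    return k


@dataclass
class TruthConfig:
    """Generative parameters for :func:`simulate_panel`.

    ``alpha``, ``beta``, ``delta``, ``gamma`` may be arrays (per disease) or
    ``None`` to draw them from their default hyperpriors.  ``base_rate`` is
    the per-person per-period diagnosis rate used to set the expected counts
    (E = population x base_rate); the study's cancers run at roughly 1 new
    case per 1000 people per 6-month period.
    """

    n_covariates: int = 2
    alpha: np.ndarray | float | None = 0.0
    beta: np.ndarray | None = None
    delta: np.ndarray | None = None
    gamma: np.ndarray | float | None = 0.0
    sigma2_phi: float = 0.3
    rho_phi: float = 25.0
    sigma2_psi: float = 0.1
    rho_psi: float = 10.0
    psi_nugget: float = 0.0
    beta_scale: float = 0.2
    delta_log_scale: float = 0.3
    base_rate: float | np.ndarray = 1.0e-3

    def __post_init__(self):
        if self.sigma2_phi < 0 or self.sigma2_psi < 0:
            raise ValueError("variances must be non-negative")
        if self.rho_phi <= 0 or self.rho_psi <= 0:
            raise ValueError("covariance ranges must be positive")
        if self.psi_nugget < 0:
            raise ValueError("nugget must be non-negative")


@dataclass
class SimulationTruth:
    """Ground-truth parameters and latent fields behind a simulated panel."""

    alpha: np.ndarray          # (D,)
    beta: np.ndarray           # (D, p)
    delta: np.ndarray          # (D,), product 1
    gamma: np.ndarray          # (D,)
    phi: np.ndarray            # (U,)
    psi: np.ndarray            # (U, D)
    sigma2_phi: float
    rho_phi: float
    sigma2_psi: float
    rho_psi: float
    theta: np.ndarray          # (U, D, T)


def _normalise_delta(delta: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale delta to product 1, rescaling phi to preserve delta*phi.

    Only an overall geometric-mean factor can be absorbed into phi; the
    remaining per-disease pattern must already be compatible.  For a common
    rescaling delta -> delta/g, phi -> g*phi keeps every delta_d * phi_i
    fixed.
    """
    delta = np.asarray(delta, float)
    if np.any(delta <= 0):
        raise ValueError("delta loadings must be positive")
    g = np.exp(np.mean(np.log(delta)))
    return delta / g, phi * g


def simulate_panel(
    geo: Geography,
    n_diseases: int,
    n_periods: int,
    truth_config: TruthConfig | None = None,
    seed: int = 0,
    level: str = "sector",
) -> tuple[CountPanel, SimulationTruth]:
    """Draw a multi-disease count panel from the shared-component model.

    Latent fields are sampled from zero-mean Gaussian processes with
    exponential covariance over the centroids of ``level``; covariates are
    drawn iid standard normal (already standardized); counts are
    Poisson(E * theta).  Returns the panel together with the generative
    truth for recovery tests.
    """
    cfg = truth_config or TruthConfig()
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    rng = np.random.default_rng(seed)

    ids = geo.unit_ids(level)
    coords = geo.centroids(level)
    pop = geo.population(level)
    U, D, T, p = len(ids), n_diseases, n_periods, cfg.n_covariates

    alpha = np.broadcast_to(np.asarray(
        rng.normal(0, 0.3, D) if cfg.alpha is None else cfg.alpha, float), (D,)).copy()
    beta = (np.asarray(cfg.beta, float) if cfg.beta is not None
            else rng.normal(0, cfg.beta_scale, size=(D, p)))
    if beta.shape != (D, p):
        raise ValueError(f"beta must have shape {(D, p)}")
    gamma = np.broadcast_to(np.asarray(
        rng.normal(0, 0.05, D) if cfg.gamma is None else cfg.gamma, float), (D,)).copy()
    delta_raw = (np.asarray(cfg.delta, float) if cfg.delta is not None
                 else np.exp(rng.normal(0, cfg.delta_log_scale, D)))

    X = rng.standard_normal(size=(U, p))
    if cfg.sigma2_phi > 0:
        K = exponential_covariance(coords, cfg.sigma2_phi, cfg.rho_phi, 1e-10 * cfg.sigma2_phi)
        phi = np.linalg.cholesky(K) @ rng.standard_normal(U)
    else:
        phi = np.zeros(U)
    if cfg.sigma2_psi > 0:
        Kp = exponential_covariance(
            coords, cfg.sigma2_psi * (1 - cfg.psi_nugget), cfg.rho_psi,
            cfg.sigma2_psi * max(cfg.psi_nugget, 1e-10))
        Lp = np.linalg.cholesky(Kp)
        psi = Lp @ rng.standard_normal(size=(U, D))
    else:
        psi = np.zeros((U, D))

    delta, phi = _normalise_delta(delta_raw, phi)

    t_idx = np.arange(1, T + 1, dtype=float)
    t_c = t_idx - t_idx.mean()
    log_theta = (
        alpha[None, :, None]
        + (X @ beta.T)[:, :, None]
        + (delta[None, :] * phi[:, None])[:, :, None]
        + psi[:, :, None]
        + (gamma[:, None] * t_c[None, :])[None, :, :]
    )
    theta = np.exp(log_theta)

    base = np.broadcast_to(np.asarray(cfg.base_rate, float), (D,))
    expected = pop[:, None, None] * base[None, :, None] * np.ones((U, D, T))
    y = rng.poisson(expected * theta).astype(float)

    cov = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)], index=ids)
    nan = np.full((U, D, T), np.nan)
    panel = CountPanel(
        units=ids,
        diseases=[f"disease_{d + 1}" for d in range(D)],
        periods=list(range(1, T + 1)),
        value=y, lo=nan.copy(), hi=nan.copy(),
        expected=expected, population=pop, covariates=cov, level=level,
    )
    truth = SimulationTruth(alpha, beta, delta, gamma, phi, psi,
                            cfg.sigma2_phi, cfg.rho_phi, cfg.sigma2_psi, cfg.rho_psi, theta)
    return panel, truth


def simulate_age_split(
    panel: CountPanel, geo: Geography, rate_ratio: float, seed: int = 0
) -> dict[str, CountPanel]:
    """Split fully observed counts into the two age bands.

    Each case is allocated to the over-50 band with probability proportional
    to pop_over50 * rate_ratio (binomial thinning), so the implied band rates
    differ by the given over50/under50 ratio.  Returns one panel per band
    whose populations are the band populations.
    """
    if panel.n_censored:
        raise ValueError("age split requires fully observed counts")
    rng = np.random.default_rng(seed)
    pop_u = geo.population(panel.level, "under50")
    pop_o = geo.population(panel.level, "over50")
    w_o = pop_o * rate_ratio
    p_over = np.where(pop_u + w_o > 0, w_o / (pop_u + w_o), 0.0)
    y = panel.value.astype(int)
    y_over = rng.binomial(y, p_over[:, None, None]).astype(float)
    y_under = y - y_over
    out = {}
    pop_all = pop_u + pop_o
    for band, yb, popb in (("under50", y_under, pop_u), ("over50", y_over, pop_o)):
        frac = np.where(pop_all > 0, popb / pop_all, 0.5)
        nan = np.full(panel.shape, np.nan)
        out[band] = CountPanel(
            list(panel.units), list(panel.diseases), list(panel.periods),
            yb, nan.copy(), nan.copy(),
            np.maximum(panel.expected * frac[:, None, None], 1e-12),
            popb, panel.covariates.copy(), panel.level,
        )
    return out


def apply_confidentiality_censoring(panel: CountPanel, threshold: int = 5) -> CountPanel:
    """Replace counts in [1, threshold] by the interval [1, threshold].

    Zero counts and counts above the threshold stay observed; expected
    counts are untouched.  Idempotent: already-censored cells keep their
    interval.
    """
    if threshold < 1:
        raise ValueError("censoring threshold must be >= 1")
    out = panel.copy()
    mask = (~np.isnan(out.value)) & (out.value >= 1) & (out.value <= threshold)
    out.lo[mask] = 1
    out.hi[mask] = threshold
    out.value[mask] = np.nan
    return out


def aggregate_to_parent(panel: CountPanel, geo: Geography, level: str) -> CountPanel:
    """Sum a fully observed child-level panel to its parent level.

    ``level`` is the target (parent) level.  Counts, expected counts and
    populations are summed over children; covariates are population-weighted
    means.
    """
    if panel.n_censored:
        raise ValueError("aggregate before censoring: panel has censored cells")
    child_level = {"sector": "fine", "district": "sector"}.get(level)
    if child_level is None:
        raise ValueError(f"cannot aggregate to level {level!r}")
    if panel.level != child_level:
        raise ValueError(f"panel is at level {panel.level!r}, expected {child_level!r}")
    pmap = geo.parent_map(child_level)
    parent_ids = geo.unit_ids(level)
    pos = {u: k for k, u in enumerate(parent_ids)}
    try:
        idx = np.array([pos[pmap[u]] for u in panel.units])
    except KeyError as e:
        raise ValueError(f"unknown parent for unit {e.args[0]!r}") from None

    P = len(parent_ids)
    U, D, T = panel.shape
    val = np.zeros((P, D, T))
    exp_ = np.zeros((P, D, T))
    np.add.at(val, idx, panel.value)
    np.add.at(exp_, idx, panel.expected)
    pop = np.zeros(P)
    np.add.at(pop, idx, panel.population)
    cov = pd.DataFrame(index=parent_ids)
    if len(panel.covariates):
        w = panel.population
        for col in panel.covariates.columns:
            num = np.zeros(P)
            den = np.zeros(P)
            np.add.at(num, idx, w * panel.covariates[col].to_numpy(float))
            np.add.at(den, idx, w)
            cov[col] = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    nan = np.full((P, D, T), np.nan)
    return CountPanel(parent_ids, list(panel.diseases), list(panel.periods),
                      val, nan.copy(), nan.copy(), exp_, pop, cov, level)


def internal_standardised_expected(panel: CountPanel) -> np.ndarray:
    """Expected counts by internal standardisation.

    E_dit = pop_i * (sum_it Y_dit / sum_it pop_i) / T per disease; censored
    cells contribute their interval midpoint.  This is how the offset is
    built for real censored data where no generative rate exists.
    """
    y = panel.midpoint_filled()
    U, D, T = panel.shape
    pop_total = panel.population.sum() * T
    rate = y.sum(axis=(0, 2)) / pop_total  # per disease, per period, per person
    e = panel.population[:, None, None] * rate[None, :, None] * np.ones((U, D, T))
    return np.maximum(e, 1e-12)


# ---------------------------------------------------------------------------
# CSV / GeoJSON I/O
# ---------------------------------------------------------------------------


def panel_to_csv(panel: CountPanel, path_or_buf) -> None:
    """Long-format CSV with intervals encoded as the source dialect "<=hi"."""
    U, D, T = panel.shape
    rows = []
    for i, u in enumerate(panel.units):
        for d, dis in enumerate(panel.diseases):
            for t, per in enumerate(panel.periods):
                v = panel.value[i, d, t]
                if np.isnan(v):
                    hi = panel.hi[i, d, t]
                    if np.isinf(hi):
                        tok = "NA"
                    elif panel.lo[i, d, t] == 1:
                        tok = CENSOR_TOKEN_FMT.format(hi=int(hi))
                    else:
                        tok = f"[{int(panel.lo[i, d, t])},{int(hi)}]"
                else:
                    tok = str(int(v))
                rows.append((u, dis, per, tok, panel.expected[i, d, t], panel.population[i]))
    pd.DataFrame(rows, columns=[
        "unit_id", "disease", "period", "count_or_interval", "expected", "population"
    ]).to_csv(path_or_buf, index=False)


def panel_from_csv(path_or_buf, covariates: pd.DataFrame | None = None,
                   level: str = "sector") -> CountPanel:
    """Read the long-format dialect written by :func:`panel_to_csv`.

    If the ``expected`` column is absent or all-zero, the offset is rebuilt
    by internal standardisation.
    """
    df = pd.read_csv(path_or_buf, dtype={"count_or_interval": str})
    units = list(dict.fromkeys(df["unit_id"]))
    diseases = list(dict.fromkeys(df["disease"]))
    periods = sorted(df["period"].unique().tolist())
    upos = {u: i for i, u in enumerate(units)}
    dpos = {d: i for i, d in enumerate(diseases)}
    tpos = {t: i for i, t in enumerate(periods)}
    shape = (len(units), len(diseases), len(periods))
    value = np.full(shape, np.nan)
    lo = np.full(shape, np.nan)
    hi = np.full(shape, np.nan)
    expected = np.zeros(shape)
    pop = np.zeros(len(units))
    has_expected = "expected" in df.columns
    for row in df.itertuples(index=False):
        i, d, t = upos[row.unit_id], dpos[row.disease], tpos[row.period]
        tok = str(row.count_or_interval).strip()
        if tok.startswith("<="):
            lo[i, d, t] = 1
            hi[i, d, t] = int(tok[2:])
        elif tok.startswith("["):
            a, b = tok.strip("[]").split(",")
            lo[i, d, t] = int(a)
            hi[i, d, t] = int(b)
        elif tok in ("NA", "nan", ""):
            lo[i, d, t] = 0
            hi[i, d, t] = np.inf
        else:
            value[i, d, t] = int(tok)
        if has_expected:
            expected[i, d, t] = row.expected
        pop[i] = row.population
    panel = CountPanel(units, diseases, periods, value, lo, hi,
                       np.maximum(expected, 1e-12), pop,
                       covariates if covariates is not None else pd.DataFrame(),
                       level)
    if not has_expected or not np.any(expected > 1e-12):
        panel.expected = internal_standardised_expected(panel)
    return panel


def geography_to_csv(geo: Geography, path_or_buf) -> None:
    geo.units.to_csv(path_or_buf, index=False)


def geography_from_csv(path_or_buf) -> Geography:
    df = pd.read_csv(path_or_buf, keep_default_na=False,
                     dtype={"unit_id": str, "parent_id": str})
    for c in ("x", "y", "pop_under50", "pop_over50"):
        df[c] = df[c].astype(float)
    return Geography(df)


def geography_polygons_geojson(geo: Geography, level: str = "sector") -> dict:
    """Voronoi polygons around the level's centroids, as a GeoJSON dict.

    Purely for mapping; the analysis itself only uses centroids.
    """
    from shapely.geometry import GeometryCollection, Point, box, mapping
    from shapely.ops import voronoi_diagram

    ids = geo.unit_ids(level)
    coords = geo.centroids(level)
    pts = [Point(xy) for xy in coords]
    pad = 5.0
    env = box(coords[:, 0].min() - pad, coords[:, 1].min() - pad,
              coords[:, 0].max() + pad, coords[:, 1].max() + pad)
    if len(pts) == 1:
        cells = [env]
    else:
        vor = voronoi_diagram(GeometryCollection(pts), envelope=env)
        # voronoi output order is arbitrary; match each cell to its seed
        cells = [None] * len(pts)
        for cell in vor.geoms:
            clipped = cell.intersection(env)
            for k, pt in enumerate(pts):
                if cells[k] is None and clipped.covers(pt):
                    cells[k] = clipped
                    break
        for k, c in enumerate(cells):
            if c is None:  # degenerate tie: fall back to nearest assignment
                cells[k] = env
    features = [
        {"type": "Feature", "properties": {"unit_id": uid},
         "geometry": mapping(cell)}
        for uid, cell in zip(ids, cells)
    ]
    return {"type": "FeatureCollection", "features": features}
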