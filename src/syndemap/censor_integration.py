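"""Censoring reduction by reconciling nested sector/district count panels.

Confidentiality censoring replaces small counts by an interval, but the same
counts are released at two nested geographic levels.  Because sector counts
within a district must sum to the district total, the two releases jointly
constrain each censored cell.  This module propagates those sum constraints
as interval bounds until a fixed point: intervals tighten, and an interval
that collapses to a point is promoted back to an exact count.

Bounds propagation yields the exact componentwise envelope of the feasible
set for a single sum constraint with interval terms, which is the structure
here (each sector cell appears in exactly one district constraint).  A
brute-force enumeration oracle is provided to verify this on small
instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_synth import CensoredCount, CountPanel, Geography

__all__ = ["ReconciliationResult", "integrate_nested_counts", "feasible_set_oracle"]


class InfeasibleCountsError(ValueError):
    """The released panels admit no integer solution (inconsistent data)."""


@dataclass
class ReconciliationResult:
    panel: CountPanel
    n_resolved: int
    n_tightened: int
    log: list[tuple] = field(default_factory=list)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log,
            columns=["unit_id", "disease", "period", "lo_before", "hi_before",
                     "lo_after", "hi_after", "resolved"],
        )


def _tighten_group(
    cell_lo: np.ndarray, cell_hi: np.ndarray, total_lo: float, total_hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed point of interval propagation for sum(cells) in [total_lo, total_hi].

    Observed cells are represented as point intervals.  Raises
    InfeasibleCountsError when any interval empties.
    """
    lo = cell_lo.astype(float).copy()
    hi = cell_hi.astype(float).copy()
    for _ in range(1000):
        s_lo, s_hi = lo.sum(), hi.sum()
        t_lo = max(total_lo, s_lo)
        t_hi = min(total_hi, s_hi)
        if t_lo > t_hi:
            raise InfeasibleCountsError("sum constraint infeasible")
        new_lo = np.maximum(lo, t_lo - (s_hi - hi))
        new_hi = np.minimum(hi, t_hi - (s_lo - lo))
        if np.any(new_lo > new_hi):
            raise InfeasibleCountsError("cell interval emptied")
        if np.array_equal(new_lo, lo) and np.array_equal(new_hi, hi):
            return lo, hi
        lo, hi = new_lo, new_hi
    return lo, hi


def integrate_nested_counts(
    sector_panel: CountPanel, district_panel: CountPanel, geo: Geography
) -> ReconciliationResult:
    """Tighten sector-level censored intervals against district totals.

    For every (district, disease, period), the sector counts nested in that
    district must sum to the district count (itself possibly an interval).
    Each censored sector interval [lo, hi] is replaced by

        [max(lo, D_lo - sum_other hi), min(hi, D_hi - sum_other lo)]

    iterated to a fixed point; point intervals are promoted to observed.
    Infeasible systems raise :class:`InfeasibleCountsError` naming the first
    offending (district, disease, period) — real-data inconsistencies must
    surface, not be repaired silently.
    """
    if sector_panel.diseases != district_panel.diseases or \
            sector_panel.periods != district_panel.periods:
        raise ValueError("sector and district panels must share diseases and periods")
    pmap = geo.parent_map("sector")
    dpos = {u: k for k, u in enumerate(district_panel.units)}
    try:
        parent_idx = np.array([dpos[pmap[u]] for u in sector_panel.units])
    except KeyError as e:
        raise ValueError(f"sector nesting mismatch: {e.args[0]!r}") from None

    out = sector_panel.copy()
    log: list[tuple] = []
    n_resolved = 0
    n_tightened = 0
    U, D, T = out.shape
    s_lo, s_hi = out.bounds()
    t_lo, t_hi = district_panel.bounds()

    for k in range(len(district_panel.units)):
        members = np.where(parent_idx == k)[0]
        if members.size == 0:
            continue
        for d in range(D):
            for t in range(T):
                glo, ghi = s_lo[members, d, t], s_hi[members, d, t]
                if np.all(glo == ghi):
                    continue  # nothing censored here
                try:
                    new_lo, new_hi = _tighten_group(glo, ghi, t_lo[k, d, t], t_hi[k, d, t])
                except InfeasibleCountsError:
                    raise InfeasibleCountsError(
                        f"inconsistent totals for district {district_panel.units[k]!r}, "
                        f"disease {out.diseases[d]!r}, period {out.periods[t]}"
                    ) from None
                for j, i in enumerate(members):
                    if glo[j] == ghi[j]:
                        continue  # was observed
                    if new_lo[j] == glo[j] and new_hi[j] == ghi[j]:
                        continue  # unchanged
                    resolved = new_lo[j] == new_hi[j]
                    log.append((out.units[i], out.diseases[d], out.periods[t],
                                glo[j], ghi[j], new_lo[j], new_hi[j], resolved))
                    if resolved:
                        out.set_cell(i, d, t, CensoredCount("observed", value=int(new_lo[j])))
                        n_resolved += 1
                    else:
                        out.set_cell(i, d, t, CensoredCount(
                            "interval", lo=int(new_lo[j]), hi=int(new_hi[j])))
                        n_tightened += 1
    return ReconciliationResult(out, n_resolved, n_tightened, log)


def feasible_set_oracle(
    district_total: CensoredCount, sector_cells: list[CensoredCount],
    max_censored: int = 8,
) -> set[tuple[int, ...]]:
    """All integer assignments to the censored cells consistent with the total.

    Exhaustive enumeration, used to verify that the bounds produced by
    :func:`integrate_nested_counts` are the exact componentwise envelope.
    Returns tuples giving a value for each *censored* cell, in input order.
    """
    cens = [c for c in sector_cells if c.is_censored]
    if len(cens) > max_censored:
        raise ValueError(f"enumeration bound exceeded: {len(cens)} > {max_censored}")
    k_obs = sum(c.value for c in sector_cells if not c.is_censored)
    t_lo, t_hi = district_total.bounds()
    if not cens:
        return {()} if t_lo <= k_obs <= t_hi else set()
    ranges = [range(int(c.lo), int(c.hi) + 1) for c in cens]
    out = set()
    for combo in itertools.product(*ranges):
        if t_lo <= k_obs + sum(combo) <= t_hi:
            out.add(combo)
    return out
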