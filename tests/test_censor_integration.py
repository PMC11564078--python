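"""Constraint propagation vs exhaustive feasible-set enumeration."""

import numpy as np
import pytest

import syndemap as sm
from syndemap.censor_integration import (InfeasibleCountsError,
                                         feasible_set_oracle,
                                         integrate_nested_counts)
from syndemap.geo_synth import CensoredCount


def _tiny_geo(n_sectors=3):
    import pandas as pd
    rows = [("D0", "district", "", 50.0, 50.0, 0.0, 0.0)]
    pu = 500.0
    for j in range(n_sectors):
        rows.append((f"S{j}", "sector", "D0", 10.0 * j, 0.0, pu, pu))
    rows[0] = ("D0", "district", "", 50.0, 50.0, pu * n_sectors, pu * n_sectors)
    df = pd.DataFrame(rows, columns=["unit_id", "level", "parent_id", "x", "y",
                                     "pop_under50", "pop_over50"])
    return sm.Geography(df)


def _panel(cells, units, level):
    """cells: list of CensoredCount, one per unit, single disease/period."""
    n = len(units)
    value = np.full((n, 1, 1), np.nan)
    lo = np.full((n, 1, 1), np.nan)
    hi = np.full((n, 1, 1), np.nan)
    for i, c in enumerate(cells):
        if c.status == "observed":
            value[i, 0, 0] = c.value
        else:
            lo[i, 0, 0], hi[i, 0, 0] = c.bounds()
    return sm.CountPanel(units, ["d"], [1], value, lo, hi,
                         np.ones((n, 1, 1)), np.full(n, 100.0), level=level)


def _integrate(district_cell, sector_cells, n_sectors=None):
    n = n_sectors or len(sector_cells)
    geo = _tiny_geo(n)
    sec = _panel(sector_cells, [f"S{j}" for j in range(n)], "sector")
    dis = _panel([district_cell], ["D0"], "district")
    return integrate_nested_counts(sec, dis, geo)


class TestExamples:
    def test_forced_resolution(self):
        """District 9 observed; 7 observed + two cells in [1,5] forces 1+1."""
        res = _integrate(CensoredCount("observed", value=9),
                         [CensoredCount("observed", value=7),
                          CensoredCount("interval", lo=1, hi=5),
                          CensoredCount("interval", lo=1, hi=5)])
        assert res.n_resolved == 2
        assert res.panel.cell(1, 0, 0).value == 1
        assert res.panel.cell(2, 0, 0).value == 1
        # brute-force check
        fs = feasible_set_oracle(CensoredCount("observed", value=9),
                                 [CensoredCount("observed", value=7),
                                  CensoredCount("interval", lo=1, hi=5),
                                  CensoredCount("interval", lo=1, hi=5)])
        assert fs == {(1, 1)}

    def test_infeasible_raises(self):
        with pytest.raises(InfeasibleCountsError, match="D0"):
            _integrate(CensoredCount("observed", value=6),
                       [CensoredCount("observed", value=6),
                        CensoredCount("interval", lo=1, hi=5)])

    def test_no_information_gained(self):
        res = _integrate(CensoredCount("interval", lo=1, hi=5),
                         [CensoredCount("interval", lo=1, hi=5)])
        assert res.n_resolved == 0 and res.n_tightened == 0
        assert res.panel.cell(0, 0, 0).bounds() == (1, 5)

    def test_oracle_trivial_cases(self):
        assert feasible_set_oracle(
            CensoredCount("observed", value=2),
            [CensoredCount("interval", lo=1, hi=5)] * 2) == {(1, 1)}
        assert feasible_set_oracle(
            CensoredCount("interval", lo=1, hi=5),
            [CensoredCount("interval", lo=1, hi=5)]) == {(k,) for k in range(1, 6)}

    def test_oracle_enumeration_bound(self):
        with pytest.raises(ValueError, match="enumeration bound"):
            feasible_set_oracle(CensoredCount("observed", value=9),
                                [CensoredCount("interval", lo=1, hi=5)] * 9)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_bounds_equal_feasible_envelope(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 7)
        truth = rng.integers(0, 9, size=n)
        cells = []
        for v in truth:
            if 1 <= v <= 5:
                cells.append(CensoredCount("interval", lo=1, hi=5))
            else:
                cells.append(CensoredCount("observed", value=int(v)))
        total = int(truth.sum())
        dcell = (CensoredCount("interval", lo=1, hi=5) if 1 <= total <= 5
                 else CensoredCount("observed", value=total))
        res = _integrate(dcell, cells)
        fs = feasible_set_oracle(dcell, cells)
        assert fs, "true configuration must be feasible"
        env_lo = np.min(np.array(list(fs)), axis=0)
        env_hi = np.max(np.array(list(fs)), axis=0)
        k = 0
        for i, c in enumerate(cells):
            if c.is_censored:
                got = res.panel.cell(i, 0, 0).bounds()
                assert got == (env_lo[k], env_hi[k])
                # soundness: the true count lies inside
                assert got[0] <= truth[i] <= got[1]
                k += 1


class TestTightenGroupProperties:
    """Hypothesis-driven soundness of the core bound-propagation kernel."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _envelope(cell_bounds, t_lo, t_hi):
        import itertools
        ranges = [range(a, b + 1) for a, b in cell_bounds]
        feas = [v for v in itertools.product(*ranges) if t_lo <= sum(v) <= t_hi]
        if not feas:
            return None
        arr = np.array(feas)
        return arr.min(axis=0), arr.max(axis=0)

    @given(st.lists(st.tuples(st.integers(0, 6), st.integers(0, 6)), min_size=1,
                    max_size=5),
           st.integers(0, 20), st.integers(0, 6))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_matches_brute_force_envelope(self, raw_cells, t_lo, width):
        from syndemap.censor_integration import (InfeasibleCountsError,
                                                 _tighten_group)
        cells = [(min(a, b), max(a, b)) for a, b in raw_cells]
        t_hi = t_lo + width
        lo = np.array([c[0] for c in cells], float)
        hi = np.array([c[1] for c in cells], float)
        want = self._envelope(cells, t_lo, t_hi)
        if want is None:
            with pytest.raises(InfeasibleCountsError):
                _tighten_group(lo, hi, t_lo, t_hi)
        else:
            got_lo, got_hi = _tighten_group(lo, hi, t_lo, t_hi)
            assert np.array_equal(got_lo, want[0])
            assert np.array_equal(got_hi, want[1])


class TestProperties:
    def _random_instance(self, rng):
        geo = sm.make_geography(20, 8, 2, seed=int(rng.integers(1e6)))
        panel, _ = sm.simulate_panel(geo, 2, 3, sm.TruthConfig(
            n_covariates=1, base_rate=8e-4), seed=int(rng.integers(1e6)))
        district = sm.aggregate_to_parent(panel, geo, "district")
        return (geo, panel, sm.apply_confidentiality_censoring(panel),
                sm.apply_confidentiality_censoring(district))

    def test_soundness_and_subset_on_simulations(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(6):
            geo, truth_panel, cens, dcens = self._random_instance(rng)
            res = integrate_nested_counts(cens, dcens, geo)
            lo, hi = res.panel.bounds()
            in_lo, in_hi = cens.bounds()
            assert np.all(lo >= in_lo) and np.all(hi <= in_hi)  # subset
            mask = np.isnan(cens.value)
            assert np.all(lo[mask] <= truth_panel.value[mask])
            assert np.all(truth_panel.value[mask] <= hi[mask])
            checked += int(mask.sum())
        assert checked > 100

    def test_idempotence(self):
        rng = np.random.default_rng(7)
        geo, _, cens, dcens = self._random_instance(rng)
        once = integrate_nested_counts(cens, dcens, geo)
        twice = integrate_nested_counts(once.panel, dcens, geo)
        assert twice.n_resolved == 0 and twice.n_tightened == 0

    def test_monotone_in_observed_information(self):
        """Replacing a censored sector by its true value never widens bounds."""
        base = [CensoredCount("interval", lo=1, hi=5),
                CensoredCount("interval", lo=1, hi=5),
                CensoredCount("interval", lo=1, hi=5)]
        dcell = CensoredCount("observed", value=7)
        res1 = _integrate(dcell, base)
        more = [CensoredCount("observed", value=3)] + base[1:]
        res2 = _integrate(dcell, more)
        for i in (1, 2):
            b1 = res1.panel.cell(i, 0, 0).bounds()
            b2 = res2.panel.cell(i, 0, 0).bounds()
            assert b2[0] >= b1[0] and b2[1] <= b1[1]
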