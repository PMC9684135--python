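"""Presence matching, the 5-year burn exclusion and quasi-absence balance."""

import numpy as np
import pandas as pd
import pytest

from firethresh import (
    StratumSpec,
    assemble_stratum_samples,
    build_burn_history,
    eligible_absence_cells,
    match_presences,
    sample_quasi_absences,
)
from firethresh import timeaxis
from firethresh.grids import make_grid


def _vpd_grid(n_lat=3, n_lon=3, n_years=1, start_year=2003, fill=None, seed=0):
    n_days = 365 * n_years
    if fill is None:
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.5, 3.5, (n_days, n_lat, n_lon))
    else:
        values = np.full((n_days, n_lat, n_lon), float(fill))
    return make_grid(
        values,
        lats=10.0 + 0.25 * np.arange(n_lat),
        lons=20.0 + 0.25 * np.arange(n_lon),
        name="vpd",
        units="kPa",
        start_year=start_year,
        steps_per_day=1,
    )


def _event(i, j, grid, date, stratum="s0"):
    return {
        "cell_lat_idx": i,
        "cell_lon_idx": j,
        "lat": float(grid.coords["lat"].values[i]),
        "lon": float(grid.coords["lon"].values[j]),
        "date": date,
        "year": int(date[:4]),
        "doy": timeaxis.parse_date(date)[1],
        "stratum": stratum,
    }


class TestMatchPresences:
    def test_event_at_cell_centre_gets_that_cells_vpd(self):
        grid = _vpd_grid()
        ev = pd.DataFrame([_event(1, 2, grid, "2003-03-01")])
        out = match_presences(ev, grid)
        doy = timeaxis.parse_date("2003-03-01")[1]
        assert out.loc[0, "vpd_kpa"] == grid.values[doy - 1, 1, 2]
        assert out.loc[0, "burned"] == 1

    def test_duplicate_events_each_yield_a_row(self):
        grid = _vpd_grid()
        ev = pd.DataFrame([_event(0, 0, grid, "2003-07-04")] * 3)
        out = match_presences(ev, grid)
        assert len(out) == 3
        assert out["vpd_kpa"].nunique() == 1

    def test_equidistant_event_resolves_deterministically(self):
        grid = _vpd_grid()
        ev = pd.DataFrame([_event(0, 0, grid, "2003-05-05")])
        # exactly between lon centres of cells (0,0) and (0,1)
        ev.loc[0, "lon"] = float(grid.coords["lon"].values[:2].mean())
        out1 = match_presences(ev, grid)
        out2 = match_presences(ev, grid)
        assert out1.loc[0, "cell_lon_idx"] == 0  # lowest index wins the tie
        assert out1.equals(out2)

    def test_out_of_bounds_events_dropped(self):
        grid = _vpd_grid()
        rows = [_event(0, 0, grid, "2003-02-02"), _event(0, 0, grid, "2003-02-03")]
        rows[1]["lat"] = 80.0
        out = match_presences(pd.DataFrame(rows), grid)
        assert len(out) == 1


class TestEligibleAbsenceCells:
    @pytest.fixture
    def toy(self):
        """10 cells; A burned 4 years before d, B burned 6 years before d."""
        stratum = StratumSpec("s0", np.ones((2, 5), dtype=bool))
        d = (2010, 100)
        cell_a, cell_b = (0, 1), (1, 3)
        history = {
            cell_a: np.array([timeaxis.date_to_ordinal(2006, 100)]),
            cell_b: np.array([timeaxis.date_to_ordinal(2004, 100)]),
        }
        return stratum, history, d, cell_a, cell_b

    def test_five_year_window_enumeration(self, toy):
        stratum, history, d, cell_a, cell_b = toy
        eligible = eligible_absence_cells(stratum, history, d, lookback_years=5)
        assert cell_a not in eligible
        assert cell_b in eligible
        assert len(eligible) == 9

    def test_lookback_zero_excludes_only_same_day(self, toy):
        stratum, history, d, cell_a, cell_b = toy
        assert len(eligible_absence_cells(stratum, history, d, lookback_years=0)) == 10
        same_day = {cell_a: np.array([timeaxis.date_to_ordinal(*d)])}
        eligible = eligible_absence_cells(stratum, same_day, d, lookback_years=0)
        assert cell_a not in eligible and len(eligible) == 9

    def test_no_history_means_all_eligible(self, toy):
        stratum, _, d, *_ = toy
        assert len(eligible_absence_cells(stratum, {}, d)) == 10

    def test_burn_just_before_window_start_is_eligible(self):
        # window [d - 5y, d) is closed below: a burn one day earlier is outside
        stratum = StratumSpec("s0", np.ones((1, 1), dtype=bool))
        d = (2010, 50)
        edge = timeaxis.date_to_ordinal(2010, 50) - 5 * 365
        history = {(0, 0): np.array([edge - 1])}
        assert (0, 0) in eligible_absence_cells(stratum, history, d)
        on_edge = {(0, 0): np.array([edge])}
        assert (0, 0) not in eligible_absence_cells(stratum, on_edge, d)


class TestSampleQuasiAbsences:
    def _events(self, grid, counts_by_year, stratum="s0"):
        rows = []
        k = 0
        for year, n in counts_by_year.items():
            for _ in range(n):
                i, j = k % grid.shape[1], (k // 3) % grid.shape[2]
                rows.append(_event(i, j, grid, f"{year}-06-{k % 28 + 1:02d}", stratum))
                k += 1
        return pd.DataFrame(rows)

    def test_per_year_counts_match_presences(self):
        grid = _vpd_grid(n_lat=6, n_lon=6, n_years=2)
        events = self._events(grid, {2003: 20, 2004: 10})
        stratum = StratumSpec("s0", np.ones((6, 6), dtype=bool))
        absences = sample_quasi_absences(events, grid, stratum, seed=1)
        counts = absences.groupby("year").size()
        assert counts[2003] == 20 and counts[2004] == 10
        assert len(absences) == 30
        assert (absences["burned"] == 0).all()

    def test_year_with_no_presences_draws_no_absences(self):
        grid = _vpd_grid(n_lat=4, n_lon=4, n_years=2)
        events = self._events(grid, {2004: 5})
        stratum = StratumSpec("s0", np.ones((4, 4), dtype=bool))
        absences = sample_quasi_absences(events, grid, stratum, seed=1)
        assert set(absences["year"]) == {2004}

    def test_seeded_determinism(self):
        grid = _vpd_grid(n_lat=5, n_lon=5)
        events = self._events(grid, {2003: 15})
        stratum = StratumSpec("s0", np.ones((5, 5), dtype=bool))
        a = sample_quasi_absences(events, grid, stratum, seed=42)
        b = sample_quasi_absences(events, grid, stratum, seed=42)
        assert a.equals(b)
        c = sample_quasi_absences(events, grid, stratum, seed=43)
        assert not a.equals(c)

    def test_no_absence_violates_exclusion_on_replay(self):
        grid = _vpd_grid(n_lat=5, n_lon=5, n_years=3)
        events = self._events(grid, {2003: 10, 2004: 10, 2005: 10})
        stratum = StratumSpec("s0", np.ones((5, 5), dtype=bool))
        history = build_burn_history(events)
        absences = sample_quasi_absences(events, grid, stratum, seed=7, history=history)
        for row in absences.itertuples(index=False):
            d = timeaxis.parse_date(row.date)
            eligible = eligible_absence_cells(stratum, history, d)
            assert (row.cell_lat_idx, row.cell_lon_idx) in eligible

    def test_draws_are_without_replacement(self):
        grid = _vpd_grid(n_lat=2, n_lon=2)
        events = self._events(grid, {2003: 30})
        stratum = StratumSpec("s0", np.ones((2, 2), dtype=bool))
        absences = sample_quasi_absences(events, grid, stratum, seed=3, history={})
        pairs = list(zip(absences["cell_lat_idx"], absences["cell_lon_idx"], absences["date"]))
        assert len(pairs) == len(set(pairs))

    def test_exhausted_pool_fails_loudly(self):
        grid = _vpd_grid(n_lat=1, n_lon=1)
        events = self._events(grid, {2003: 400})
        stratum = StratumSpec("s0", np.ones((1, 1), dtype=bool))
        with pytest.raises(RuntimeError, match="2003"):
            sample_quasi_absences(events, grid, stratum, seed=1, history={})

    def test_draws_uniform_over_eligible_pool(self):
        # chi-squared sanity: 2 eligible cells, counts over many seeds ~ 50/50
        grid = _vpd_grid(n_lat=1, n_lon=2)
        events = self._events(grid, {2003: 4})
        stratum = StratumSpec("s0", np.ones((1, 2), dtype=bool))
        counts = np.zeros(2)
        for seed in range(1000):
            out = sample_quasi_absences(events, grid, stratum, seed=seed, history={})
            for j in out["cell_lon_idx"]:
                counts[j] += 1
        total = counts.sum()
        chi2 = np.sum((counts - total / 2) ** 2 / (total / 2))
        assert chi2 < 10.83  # p > 0.001 for 1 dof


class TestAssemble:
    def test_concatenation_and_balance(self):
        grid = _vpd_grid(n_lat=6, n_lon=6)
        events = pd.DataFrame([_event(i % 6, i // 6 % 6, grid, "2003-08-15") for i in range(150)])
        presences = match_presences(events, grid)
        stratum = StratumSpec("s0", np.ones((6, 6), dtype=bool))
        absences = sample_quasi_absences(events, grid, stratum, seed=5, history={})
        combined = assemble_stratum_samples(presences, absences, seed=9)
        assert len(combined) == 300
        assert combined["burned"].mean() == 0.5
        per_year = combined.groupby(["year", "burned"]).size().unstack()
        assert (per_year[0] == per_year[1]).all()

    def test_empty_stratum_yields_empty_table(self):
        empty = pd.DataFrame(columns=["vpd_kpa", "burned", "year", "stratum"])
        out = assemble_stratum_samples(empty, empty, seed=1)
        assert out.empty

    def test_shuffle_is_deterministic(self):
        pres = pd.DataFrame({"vpd_kpa": [1, 2], "burned": [1, 1], "year": 2003, "stratum": "s0"})
        abse = pd.DataFrame({"vpd_kpa": [3, 4], "burned": [0, 0], "year": 2003, "stratum": "s0"})
        assert assemble_stratum_samples(pres, abse, seed=2).equals(
            assemble_stratum_samples(pres, abse, seed=2)
        )
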