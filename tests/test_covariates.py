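"""Ring geometry, beetle pressure, border distance, aspect, table assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpbselect import (
    CellStatus,
    GridSpec,
    aspect_transform,
    assemble_table,
    beetle_pressure,
    beetle_pressure_lattice,
    distance_to_border,
    ring_offsets,
)
from mpbselect.covariates import PRESSURE_MAX, RING_WEIGHTS
from mpbselect.errors import (
    DegenerateBorderError,
    MissingColumnsError,
    OutOfGridError,
    RingIndexError,
    YearGapError,
)

A, C, U = CellStatus.ABSENT, CellStatus.INFESTED_CONTROLLED, CellStatus.INFESTED_UNCONTROLLED


def brute_force_pressure(states, row, col, status):
    """Independent oracle: enumerate all offsets within distance 3."""
    total = 0.0
    for dr in range(-3, 4):
        for dc in range(-3, 4):
            d = math.hypot(dr, dc)
            if d > 3:
                continue
            rr, cc = row + dr, col + dc
            if not (0 <= rr < states.shape[0] and 0 <= cc < states.shape[1]):
                continue
            if states[rr, cc] != status:
                continue
            ring = 0 if d == 0 else math.ceil(d - 1e-12)
            total += RING_WEIGHTS[ring]
    return total


class TestRingGeometry:
    def test_cardinalities(self):
        assert [len(ring_offsets(r)) for r in (1, 2, 3)] == [4, 8, 16]

    def test_ring1_is_rook_adjacency(self):
        assert ring_offsets(1) == {(0, 1), (0, -1), (1, 0), (-1, 0)}

    def test_union_matches_distance_band_enumeration(self):
        union = set().union(*(ring_offsets(r) for r in (1, 2, 3)))
        expected = {
            (dr, dc)
            for dr in range(-3, 4)
            for dc in range(-3, 4)
            if 0 < math.hypot(dr, dc) <= 3
        }
        assert union == expected
        assert all(
            not ring_offsets(a) & ring_offsets(b) for a in (1, 2, 3) for b in (1, 2, 3) if a != b
        )

    @pytest.mark.parametrize("bad", [0, 4, -1])
    def test_invalid_ring_index(self, bad):
        with pytest.raises(RingIndexError):
            ring_offsets(bad)


class TestBeetlePressure:
    @pytest.mark.parametrize("ring,weight", [(1, 0.5), (2, 0.25), (3, 0.125)])
    def test_lone_uncontrolled_cell_per_ring(self, ring, weight):
        states = np.zeros((7, 7), dtype=int)
        dr, dc = sorted(ring_offsets(ring))[0]
        states[3 + dr, 3 + dc] = U
        bp = beetle_pressure(states, (3, 3))
        assert bp.I_u == weight
        assert bp.I_c == 0.0

    def test_empty_neighborhood(self):
        bp = beetle_pressure(np.zeros((7, 7), dtype=int), (3, 3))
        assert bp.I_c == bp.I_u == 0.0

    def test_fully_uncontrolled_neighborhood_reaches_bound(self):
        states = np.full((7, 7), int(U))
        bp = beetle_pressure(states, (3, 3))
        assert bp.I_u == PRESSURE_MAX == brute_force_pressure(states, 3, 3, U)
        assert bp.I_c == 0.0

    def test_statuses_do_not_mix(self):
        states = np.zeros((7, 7), dtype=int)
        states[3, 3] = C
        states[3, 4] = U
        bp = beetle_pressure(states, (3, 3))
        assert bp.I_c == 1.0 and bp.I_u == 0.5

    def test_offgrid_neighbors_contribute_zero(self):
        states = np.full((7, 7), int(U))
        bp = beetle_pressure(states, (0, 0))  # corner: most of the window is off-grid
        assert bp.I_u == brute_force_pressure(states, 0, 0, U) < PRESSURE_MAX

    def test_cell_outside_grid_rejected(self):
        with pytest.raises(OutOfGridError):
            beetle_pressure(np.zeros((5, 5), dtype=int), (5, 0))

    def test_monotone_in_added_infestations(self, rng):
        states = (rng.random((9, 9)) < 0.2).astype(int) * int(U)
        base = beetle_pressure(states, (4, 4)).I_u
        empty = np.argwhere(states == 0)
        r, c = empty[rng.integers(len(empty))]
        states[r, c] = U
        assert beetle_pressure(states, (4, 4)).I_u >= base

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_lattice_equals_per_cell_oracle(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.choice([0, 1, 2], size=(8, 8), p=[0.7, 0.15, 0.15])
        I_c, I_u = beetle_pressure_lattice(states)
        for row in range(8):
            for col in range(8):
                assert I_c[row, col] == pytest.approx(
                    brute_force_pressure(states, row, col, C)
                )
                assert I_u[row, col] == pytest.approx(
                    brute_force_pressure(states, row, col, U)
                )


class TestDistanceToBorder:
    def test_on_border_is_zero(self):
        grid = GridSpec(3, 3, 100.0)
        border = [(0.0, 50.0), (300.0, 50.0)]  # passes through row-0 centers
        assert distance_to_border(grid, np.array(border), (0, 1)) == 0.0

    def test_three_rows_north_of_straight_border(self):
        grid = GridSpec(5, 5, 100.0)
        border = np.array([(-100.0, -50.0), (600.0, -50.0)])
        # row 2 center y = 250, gap to y = -50 is 300 m
        assert distance_to_border(grid, border, (2, 0)) == pytest.approx(300.0)

    def test_translation_invariance(self):
        border = np.array([(0.0, -50.0), (500.0, -50.0)])
        d0 = distance_to_border(GridSpec(4, 4, 100.0), border, (3, 2))
        shift = np.array([1234.5, -987.0])
        d1 = distance_to_border(
            GridSpec(4, 4, 100.0, origin=tuple(shift)), border + shift, (3, 2)
        )
        assert d0 == pytest.approx(d1)

    def test_degenerate_border_rejected(self):
        with pytest.raises(DegenerateBorderError):
            distance_to_border(GridSpec(2, 2), np.array([(0.0, 0.0), (0.0, 0.0)]), (0, 0))

    def test_surface_matches_pointwise(self):
        grid = GridSpec(4, 6, 100.0)
        border = np.array([(0.0, -50.0), (200.0, 30.0), (650.0, -50.0)])
        surface = distance_to_border(grid, border)
        assert surface.shape == grid.shape
        for cell in [(0, 0), (2, 3), (3, 5)]:
            assert surface[cell] == pytest.approx(distance_to_border(grid, border, cell))


class TestAspectTransform:
    @pytest.mark.parametrize(
        "azimuth,expected",
        [
            (0.0, (1.0, 0.0)),
            (90.0, (0.0, 1.0)),
            (225.0, (-math.sqrt(2) / 2, -math.sqrt(2) / 2)),
            (450.0, (0.0, 1.0)),  # wrapped modulo 360
        ],
    )
    def test_cardinal_directions(self, azimuth, expected):
        N, E = aspect_transform(azimuth)
        assert N == pytest.approx(expected[0], abs=1e-12)
        assert E == pytest.approx(expected[1], abs=1e-12)

    def test_bounded(self, rng):
        N, E = aspect_transform(rng.uniform(-720, 720, size=100))
        assert np.all(np.abs(N) <= 1) and np.all(np.abs(E) <= 1)


def _toy_census(n=4, years=(2000, 2001, 2002)):
    rows = []
    for year in years:
        for cid in range(n * n):
            rows.append(
                {
                    "cell_id": cid,
                    "row": cid // n,
                    "col": cid % n,
                    "year": year,
                    "response": 0,
                    "status": "absent",
                    "SMI": 50.0,
                }
            )
    return pd.DataFrame(rows)


class TestAssembleTable:
    def test_first_year_dropped_and_row_count(self, small_outbreak):
        cfg, states, census = small_outbreak
        table = assemble_table(census)
        n_cells = cfg.grid.n_cells
        n_years = len(cfg.year_list)
        assert len(table) == n_cells * (n_years - 1)
        assert table["year"].min() == cfg.year_list[1]
        assert not table.isna().any().any()

    def test_univoltine_source_window(self):
        census = _toy_census()
        # cell (1, 1) uncontrolled in 2000 only
        mask = (census["year"] == 2000) & (census["cell_id"] == 5)
        census.loc[mask, ["status", "response"]] = ["infested_uncontrolled", 1]
        table = assemble_table(census)
        neighbor = table[(table["cell_id"] == 6) & (table["year"] == 2001)]
        assert neighbor["I_u"].item() == 0.5  # ring-1 source the following year
        neighbor_later = table[(table["cell_id"] == 6) & (table["year"] == 2002)]
        assert neighbor_later["I_u"].item() == 0.0  # but never two years on

    def test_row_shuffle_invariance(self, rng):
        census = _toy_census()
        census.loc[census.sample(8, random_state=3).index, "status"] = (
            "infested_controlled"
        )
        shuffled = census.sample(frac=1.0, random_state=11).reset_index(drop=True)
        pd.testing.assert_frame_equal(assemble_table(census), assemble_table(shuffled))

    def test_year_gap_rejected(self):
        census = _toy_census(years=(2000, 2002, 2003))
        with pytest.raises(YearGapError):
            assemble_table(census)

    def test_missing_column_named(self):
        census = _toy_census().drop(columns=["year"])
        with pytest.raises(MissingColumnsError) as err:
            assemble_table(census)
        assert "year" in err.value.columns
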