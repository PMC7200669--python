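"""Derived covariates: neighborhood beetle pressure, border distance, aspect.

Beetle pressure summarizes the previous year's infestations in a 3-cell
radius around each focal cell, split by management outcome:

    I_u = [focal uncontrolled] + 0.5 * (# uncontrolled in ring 1)
        + 0.25 * (# uncontrolled in ring 2) + 0.125 * (# uncontrolled in ring 3)

and identically for I_c with controlled infestations. Rings are Euclidean
center-to-center distance bands r - 1 < d <= r (in cell units), which yields
the 4 / 8 / 16 adjacent-cell cardinalities. Because the beetle is univoltine,
only the immediately preceding year's states enter: an infested tree is a
beetle source for the following year and not the years after that.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point

from .errors import (
    DegenerateBorderError,
    MissingColumnsError,
    OutOfGridError,
    RingIndexError,
    YearGapError,
)
from .grid import CellStatus, GridSpec

#: Ring weights of the beetle-pressure index, keyed by ring index
#: (0 = the focal cell itself).
RING_WEIGHTS = {0: 1.0, 1: 0.5, 2: 0.25, 3: 0.125}

#: Upper bound on I_c or I_u: every cell in the neighborhood infested,
#: 1 + 0.5*4 + 0.25*8 + 0.125*16.
PRESSURE_MAX = 7.0


@dataclass(frozen=True)
class BeetlePressure:
    """Weighted previous-year infestation counts around one cell."""

    I_c: float
    I_u: float


def ring_offsets(r: int) -> frozenset[tuple[int, int]]:
    """(dr, dc) offsets of neighborhood ring ``r`` in {1, 2, 3}.

    Ring ``r`` collects the offsets whose center-to-center Euclidean
    distance d = sqrt(dr^2 + dc^2) satisfies r - 1 < d <= r.
    """
    if r not in (1, 2, 3):
        raise RingIndexError(f"ring index must be 1, 2 or 3, got {r!r}")
    offsets = []
    for dr in range(-3, 4):
        for dc in range(-3, 4):
            d = math.hypot(dr, dc)
            if r - 1 < d <= r:
                offsets.append((dr, dc))
    return frozenset(offsets)


def pressure_kernel() -> np.ndarray:
    """7x7 convolution kernel carrying the ring weights (center = 1)."""
    k = np.zeros((7, 7))
    k[3, 3] = RING_WEIGHTS[0]
    for r in (1, 2, 3):
        for dr, dc in ring_offsets(r):
            k[3 + dr, 3 + dc] = RING_WEIGHTS[r]
    return k


def beetle_pressure(states: np.ndarray, cell: tuple[int, int]) -> BeetlePressure:
    """Beetle pressure at one cell from the previous year's status lattice.

    Off-grid neighbors contribute 0 (the census grid is a complete
    rectangle; there is no wraparound or renormalization at the edges).
    """
    states = np.asarray(states)
    row, col = cell
    if not (0 <= row < states.shape[0] and 0 <= col < states.shape[1]):
        raise OutOfGridError(f"cell {cell} outside lattice {states.shape}")

    def weighted(status: CellStatus) -> float:
        total = float(states[row, col] == status) * RING_WEIGHTS[0]
        for r in (1, 2, 3):
            count = 0
            for dr, dc in ring_offsets(r):
                rr, cc = row + dr, col + dc
                if 0 <= rr < states.shape[0] and 0 <= cc < states.shape[1]:
                    count += states[rr, cc] == status
            total += RING_WEIGHTS[r] * count
        return total

    return BeetlePressure(
        I_c=weighted(CellStatus.INFESTED_CONTROLLED),
        I_u=weighted(CellStatus.INFESTED_UNCONTROLLED),
    )


def beetle_pressure_lattice(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (I_c, I_u) surfaces for a whole previous-year lattice.

    Equivalent to calling :func:`beetle_pressure` at every cell; implemented
    as a convolution with the ring-weight kernel and zero padding.
    """
    states = np.asarray(states)
    kernel = pressure_kernel()
    controlled = (states == CellStatus.INFESTED_CONTROLLED).astype(float)
    uncontrolled = (states == CellStatus.INFESTED_UNCONTROLLED).astype(float)
    I_c = ndimage.convolve(controlled, kernel, mode="constant", cval=0.0)
    I_u = ndimage.convolve(uncontrolled, kernel, mode="constant", cval=0.0)
    return I_c, I_u


def distance_to_border(
    grid: GridSpec, border: np.ndarray | LineString, cell: tuple[int, int] | None = None
) -> float | np.ndarray:
    """Minimum Euclidean distance from cell center(s) to a border polyline.

    ``border`` is either a shapely LineString or an (n, 2) vertex array in
    meters. With ``cell=None`` the full (n_rows, n_cols) distance surface is
    returned.
    """
    if not isinstance(border, LineString):
        border = np.asarray(border, dtype=float)
        if border.ndim != 2 or border.shape[0] < 2 or border.shape[1] != 2:
            raise DegenerateBorderError("border needs at least two (x, y) vertices")
        border = LineString(border)
    if border.length == 0:
        raise DegenerateBorderError("border polyline has zero length")

    centers = grid.cell_centers()
    if cell is not None:
        row, col = cell
        if not grid.contains(row, col):
            raise OutOfGridError(f"cell {cell} outside grid {grid.shape}")
        return float(border.distance(Point(centers[row, col])))
    flat = centers.reshape(-1, 2)
    from shapely import points as shapely_points

    return border.distance(shapely_points(flat)).reshape(grid.shape)


def aspect_transform(azimuth: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Northerness/easterness of a slope aspect.

    ``azimuth`` is in degrees clockwise from north (wrapped modulo 360);
    N = cos(azimuth), E = sin(azimuth), both in [-1, 1].
    """
    rad = np.deg2rad(np.asarray(azimuth, dtype=float) % 360.0)
    return np.cos(rad), np.sin(rad)


CENSUS_KEY_COLUMNS = ["cell_id", "row", "col", "year", "response", "status"]


def assemble_table(census: pd.DataFrame) -> pd.DataFrame:
    """Build the modeling table: census rows with I_c and I_u joined.

    Beetle pressure for year t is computed from the year t-1 status lattice,
    so the first census year (whose predecessor is unobserved) is dropped.
    The result has one row per cell-year for the remaining years, sorted by
    (year, cell_id), with no missing values.
    """
    missing = set(CENSUS_KEY_COLUMNS) - set(census.columns)
    if missing:
        raise MissingColumnsError(missing)
    years = sorted(census["year"].unique())
    if len(years) < 2:
        raise YearGapError("need at least two census years to derive beetle pressure")
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        raise YearGapError(f"census years are not contiguous: {years}")

    n_rows = int(census["row"].max()) + 1
    n_cols = int(census["col"].max()) + 1

    from .grid import LABEL_TO_STATUS

    status_codes = census["status"].map(lambda s: int(LABEL_TO_STATUS[s]))
    pieces = []
    for prev_year, year in zip(years, years[1:]):
        prev = census.loc[census["year"] == prev_year]
        lattice = np.zeros((n_rows, n_cols), dtype=np.int8)
        lattice[prev["row"].to_numpy(), prev["col"].to_numpy()] = status_codes.loc[
            prev.index
        ].to_numpy()
        I_c, I_u = beetle_pressure_lattice(lattice)
        rows = census.loc[census["year"] == year].copy()
        rows["I_c"] = I_c[rows["row"].to_numpy(), rows["col"].to_numpy()]
        rows["I_u"] = I_u[rows["row"].to_numpy(), rows["col"].to_numpy()]
        pieces.append(rows)
    table = pd.concat(pieces, ignore_index=True)
    table = table.sort_values(["year", "cell_id"], kind="stable").reset_index(drop=True)
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise MissingColumnsError(bad)
    return table
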