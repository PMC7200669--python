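"""Census grid geometry and per-cell infestation states.

The analysis discretizes the landscape into square cells (100 m by default,
matching the size of the management survey plots). Each cell has exactly one
status per census year: not infested, infested with all attacked trees
controlled by managers, or infested with uncontrolled (missed) trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class CellStatus(IntEnum):
    """Infestation status of one cell in one census year."""

    ABSENT = 0
    INFESTED_CONTROLLED = 1
    INFESTED_UNCONTROLLED = 2


STATUS_LABELS = {
    CellStatus.ABSENT: "absent",
    CellStatus.INFESTED_CONTROLLED: "infested_controlled",
    CellStatus.INFESTED_UNCONTROLLED: "infested_uncontrolled",
}
LABEL_TO_STATUS = {v: k for k, v in STATUS_LABELS.items()}


@dataclass(frozen=True)
class GridSpec:
    """A rectangular grid of square cells.

    Rows and columns are 0-based; row 0 is the southern edge of the grid
    (smallest y). The center of cell (r, c) sits at
    ``origin + ((c + 0.5) * cell_size, (r + 0.5) * cell_size)``.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> np.ndarray:
        """(n_rows, n_cols, 2) array of cell-center (x, y) coordinates."""
        rr, cc = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        x = self.origin[0] + (cc + 0.5) * self.cell_size
        y = self.origin[1] + (rr + 0.5) * self.cell_size
        return np.stack([x, y], axis=-1)

    def cell_ids(self) -> np.ndarray:
        """Row-major cell ids, shape (n_rows, n_cols)."""
        return np.arange(self.n_cells).reshape(self.shape)

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols
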