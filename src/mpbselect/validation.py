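"""Leave-one-year-out cross-validation and predicted-risk rasters.

Model skill is assessed with folds defined by census year within an
outbreak phase: train on all the phase's years but one, score the held-out
year, repeat until every year has been tested, and average AUROC/AUPR over
folds. Risk maps evaluate a fitted model's probabilities cell by cell for
one year and serialize them as a plain-text raster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateResponseError, MissingColumnsError
from .grid import GridSpec
from .logistic import LogisticFit, fit_logistic
from .metrics import aupr, auroc

logger = logging.getLogger(__name__)


@dataclass
class ValidationResult:
    """Per-fold and mean AUROC/AUPR for one covariate subset."""

    subset: tuple[str, ...]
    folds: pd.DataFrame  # columns: year, auroc, aupr (aupr NaN if undefined)
    mean_auroc: float
    mean_aupr: float


def loyo_cv(
    table: pd.DataFrame,
    subset: list[str],
    response: str = "response",
    year_col: str = "year",
) -> ValidationResult:
    """Leave-one-year-out cross-validation of one covariate subset.

    One fold per distinct year. A fold whose held-out year lacks positives
    has no defined AUPR; such folds are dropped from the AUPR mean with a
    logged warning (the AUROC mean likewise requires both classes).
    """
    years = sorted(table[year_col].unique())
    if len(years) < 2:
        raise ValueError("leave-one-year-out CV needs at least two years")
    rows = []
    for held_out in years:
        train = table[table[year_col] != held_out]
        test = table[table[year_col] == held_out]
        fit = fit_logistic(train, train[response].to_numpy(dtype=float), subset)
        scores = fit.predict(test)
        labels = test[response].to_numpy()
        try:
            fold_auroc = auroc(scores, labels)
        except DegenerateResponseError:
            logger.warning(
                "fold %s has a single response class; AUROC undefined", held_out
            )
            fold_auroc = np.nan
        try:
            fold_aupr = aupr(scores, labels)
        except DegenerateResponseError:
            logger.warning(
                "fold %s has no positives; AUPR undefined, dropped from mean",
                held_out,
            )
            fold_aupr = np.nan
        rows.append({"year": held_out, "auroc": fold_auroc, "aupr": fold_aupr})
    folds = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN mean
        mean_auroc = float(np.nanmean(folds["auroc"]))
        mean_aupr = float(np.nanmean(folds["aupr"]))
    return ValidationResult(
        subset=tuple(subset), folds=folds, mean_auroc=mean_auroc, mean_aupr=mean_aupr
    )


def predict_risk_map(
    fit: LogisticFit, year_table: pd.DataFrame, grid: GridSpec
) -> np.ndarray:
    """Predicted infestation probability per cell for one year.

    ``year_table`` holds that year's covariate rows with ``row``/``col``
    columns; returns an (n_rows, n_cols) array of probabilities in (0, 1).
    """
    needed = {"row", "col"} | set(fit.covariates)
    missing = needed - set(year_table.columns)
    if missing:
        raise MissingColumnsError(missing)
    pi = fit.predict(year_table)
    surface = np.full(grid.shape, np.nan)
    surface[
        year_table["row"].to_numpy(int), year_table["col"].to_numpy(int)
    ] = pi
    return surface


def write_raster(path, surface: np.ndarray, grid: GridSpec) -> None:
    """Write a probability surface as an ESRI-ASCII-style text raster.

    Values are written row-major from the northern edge down (the ASCII-grid
    convention), 6 significant digits.
    """
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6g}\n")
        fh.write(f"cellsize {grid.cell_size:.6g}\n")
        fh.write("NODATA_value -9999\n")
        filled = np.where(np.isnan(surface), -9999.0, surface)
        for row in filled[::-1]:  # row 0 is the southern edge internally
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_raster(path) -> tuple[np.ndarray, GridSpec]:
    """Read a raster written by :func:`write_raster`."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    surface = np.asarray(rows, dtype=float)[::-1]
    surface[surface == header.get("nodata_value", -9999.0)] = np.nan
    return surface, grid


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
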