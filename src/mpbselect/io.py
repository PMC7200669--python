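"""CSV and YAML round-trips for censuses, borders, temperatures, and configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .covariates import CENSUS_KEY_COLUMNS
from .errors import MissingColumnsError
from .grid import GridSpec
from .synthetic import SimulationConfig


def write_census(census: pd.DataFrame, path) -> None:
    missing = set(CENSUS_KEY_COLUMNS) - set(census.columns)
    if missing:
        raise MissingColumnsError(missing)
    census.to_csv(path, index=False)


def read_census(path) -> pd.DataFrame:
    try:
        census = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise MissingColumnsError(CENSUS_KEY_COLUMNS) from exc
    missing = set(CENSUS_KEY_COLUMNS) - set(census.columns)
    if missing:
        raise MissingColumnsError(missing)
    return census


def write_border(border: np.ndarray, path) -> None:
    pd.DataFrame(border, columns=["x", "y"]).to_csv(path, index=False)


def read_border(path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise MissingColumnsError(missing)
    return df[["x", "y"]].to_numpy(dtype=float)


def read_temperature_series(path) -> pd.DataFrame:
    """Daily temperature CSV with columns julian_day, tmean_c (+ optional cell_id)."""
    df = pd.read_csv(path)
    missing = {"julian_day", "tmean_c"} - set(df.columns)
    if missing:
        raise MissingColumnsError(missing)
    return df


def config_to_yaml(config: SimulationConfig, path) -> None:
    payload = {
        "grid": {
            "n_rows": config.grid.n_rows,
            "n_cols": config.grid.n_cols,
            "cell_size": config.grid.cell_size,
            "origin": list(config.grid.origin),
        },
        "years": list(config.years),
        "beta_true": dict(config.beta_true),
        "p_detect": config.p_detect,
        "border_pressure": config.border_pressure,
        "seed_distance": config.seed_distance,
        "weather_forcing": {int(k): float(v) for k, v in config.weather_forcing.items()},
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    g = payload["grid"]
    return SimulationConfig(
        grid=GridSpec(
            n_rows=int(g["n_rows"]),
            n_cols=int(g["n_cols"]),
            cell_size=float(g.get("cell_size", 100.0)),
            origin=tuple(g.get("origin", (0.0, 0.0))),
        ),
        years=tuple(payload["years"]),
        beta_true={k: float(v) for k, v in payload.get("beta_true", {}).items()},
        p_detect=float(payload.get("p_detect", 0.7)),
        border_pressure=float(payload.get("border_pressure", 0.25)),
        seed_distance=float(payload.get("seed_distance", 400.0)),
        weather_forcing={
            int(k): float(v) for k, v in payload.get("weather_forcing", {}).items()
        },
        seed=int(payload.get("seed", 0)),
    )
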