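"""CSV and YAML I/O for the pipeline's external interfaces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .events import GridSpec, ModelFit, MortalitySeries
from .synthetic import SyntheticConfig
from .thermal import DailyIndicatorSeries

__all__ = [
    "read_daily_joined_csv",
    "write_daily_joined_csv",
    "write_indicator_csv",
    "fit_table_frame",
    "load_grid_spec",
    "load_synthetic_config",
]


def read_daily_joined_csv(
    path, indicator_name: str = "Tmax", region: str = "file", age_group: str = "all"
) -> tuple[DailyIndicatorSeries, MortalitySeries]:
    """Read the joined daily table ``date,tx,deaths,population``."""
    frame = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "tx", "deaths", "population"}
    if not required.issubset(frame.columns):
        raise InvalidInputError(
            f"joined CSV must have columns {sorted(required)}, got {list(frame.columns)}"
        )
    dates = tuple(d.date() for d in frame["date"])
    series = DailyIndicatorSeries(
        dates, frame["tx"].to_numpy(dtype=float), indicator_name
    )
    mortality = MortalitySeries(
        dates,
        frame["deaths"].to_numpy(dtype=float),
        frame["population"].to_numpy(dtype=float),
        region,
        age_group,
    )
    return series, mortality


def write_daily_joined_csv(
    path, series: DailyIndicatorSeries, mortality: MortalitySeries
) -> None:
    frame = pd.DataFrame(
        {
            "date": pd.to_datetime(list(series.dates)).strftime("%Y-%m-%d"),
            "tx": series.values,
            "deaths": mortality.deaths.astype(int),
            "population": mortality.population,
        }
    )
    frame.to_csv(path, index=False)


def write_indicator_csv(path, series: DailyIndicatorSeries) -> None:
    """Daily indicator output, ``date,indicator,value``."""
    frame = series.to_frame()
    frame["date"] = frame["date"].dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False)


def fit_table_frame(fits: list[ModelFit]) -> pd.DataFrame:
    """Fit table mirroring the headline report columns."""
    return pd.DataFrame(
        {
            "indicator": [f.indicator_name for f in fits],
            "stratum": [f.stratum for f in fits],
            "tth": [f.tth for f in fits],
            "lag": [f.lag for f in fits],
            "alpha": [f.alpha for f in fits],
            "p0": [f.p0 for f in fits],
            "r2": [f.r2 for f in fits],
            "sig": [f.significance for f in fits],
            "annual_memr": [f.annual_memr for f in fits],
            "n_events": [f.n_events for f in fits],
        }
    )


def load_grid_spec(config: dict | str | Path | None) -> GridSpec:
    """GridSpec from a YAML path or an already-parsed mapping."""
    if config is None:
        return GridSpec()
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    section = config.get("grid", config)
    kwargs = {}
    if "thresholds" in section:
        kwargs["thresholds"] = tuple(float(t) for t in section["thresholds"])
    elif {"tth_min", "tth_max"}.issubset(section):
        kwargs["thresholds"] = tuple(
            float(t) for t in np.arange(section["tth_min"], section["tth_max"] + 1)
        )
    if "lags" in section:
        kwargs["lags"] = tuple(int(l) for l in section["lags"])
    elif "max_lag" in section:
        kwargs["lags"] = tuple(range(0, int(section["max_lag"]) + 1))
    for key in ("min_events", "min_run"):
        if key in section:
            kwargs[key] = int(section[key])
    return GridSpec(**kwargs)


def load_synthetic_config(config: dict | str | Path | None, seed: int | None = None) -> SyntheticConfig:
    """SyntheticConfig from a YAML path or mapping; ``seed`` overrides."""
    if config is None:
        config = {}
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    section = dict(config.get("synthetic", config))
    known = set(SyntheticConfig.__dataclass_fields__)
    section = {k: v for k, v in section.items() if k in known}
    if seed is not None:
        section["seed"] = int(seed)
    return SyntheticConfig(**section)
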