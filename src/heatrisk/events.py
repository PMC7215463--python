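"""Heatwave event extraction and magnitude–mortality regression.

A heatwave event is a maximal run of at least ``min_run`` consecutive days
on which the daily-maximum indicator Tx strictly exceeds a threshold Tth.
Each event carries a magnitude

    Mi = log10(1 + Σ_event (Tx(j) − Tth))

and an event-mean daily mortality rate p̄i averaged over the event days
plus Li lag days, where Li is the nominal lag L truncated when the next
event begins or the series ends (delayed deaths are attributed to the
nearer event).  The exposure–response model is the per-event ordinary
least squares regression

    p̄i = p0 + α·Mi + ε

whose slope α is the heat sensitivity (10⁻⁶·day⁻¹ per unit magnitude) and
intercept p0 the base mortality rate.  The free pair (Tth, L) is chosen by
exhaustive grid search maximising R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, NoModelError, UnfitTableError
from .thermal import DailyIndicatorSeries

__all__ = [
    "MortalitySeries",
    "HeatwaveEvent",
    "ModelFit",
    "GridSpec",
    "extract_events",
    "event_magnitude",
    "assign_lag_windows",
    "event_mean_mortality",
    "fit_event_regression",
    "build_events",
    "grid_search",
    "significance_tier",
]

#: Scale of all mortality rates in this package: 10⁻⁶ per person per day.
RATE_SCALE = 1e-6


@dataclass(frozen=True)
class MortalitySeries:
    """Daily death counts and population for one stratum.

    ``deaths`` are non-negative integers; ``population`` is positive
    (daily values, typically interpolated from annual releases).  The
    daily mortality rate ``p(j) = deaths(j)/N(j)`` is exposed in units of
    10⁻⁶·day⁻¹ via :meth:`daily_rate`.
    """

    dates: tuple[date, ...]
    deaths: np.ndarray
    population: np.ndarray
    region: str = "synthetic"
    age_group: str = "all"  # one of {"0-64", "65+", "all"}

    def __post_init__(self) -> None:
        deaths = np.asarray(self.deaths, dtype=float)
        pop = np.asarray(self.population, dtype=float)
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "population", pop)
        if not (len(self.dates) == len(deaths) == len(pop)):
            raise InvalidInputError("dates, deaths and population must align")
        if np.any(deaths < 0):
            raise InvalidInputError("deaths must be non-negative")
        if np.any(pop <= 0):
            raise InvalidInputError("population must be positive")

    def __len__(self) -> int:
        return len(self.dates)

    def daily_rate(self) -> np.ndarray:
        """Daily mortality rate in 10⁻⁶·day⁻¹."""
        return self.deaths / self.population / RATE_SCALE

    @property
    def stratum(self) -> str:
        return f"{self.region}/{self.age_group}"


@dataclass(frozen=True)
class HeatwaveEvent:
    """One extracted heatwave event with its lag window attached.

    ``start_index`` is the 0-based day offset into the daily series,
    ``duration`` the number of exceedance days (≥ 3), ``lag`` the
    truncated lag Li, ``magnitude`` the log₁₀ exceedance magnitude Mi,
    ``mean_rate`` the event-mean mortality rate p̄i (10⁻⁶·day⁻¹) and
    ``mean_population`` the mean population over the Di+Li window.
    """

    start_index: int
    duration: int
    lag: int
    magnitude: float
    mean_rate: float = float("nan")
    mean_population: float = float("nan")

    @property
    def window_days(self) -> int:
        """Length of the attribution window, Di + Li days."""
        return self.duration + self.lag


@dataclass(frozen=True)
class ModelFit:
    """A fitted exposure–response model for one (indicator, stratum).

    ``alpha`` (slope, heat sensitivity) and ``p0`` (intercept, base rate)
    are in 10⁻⁶·day⁻¹; ``r2`` is the squared Pearson correlation between
    event magnitudes and event-mean rates, ``p_value`` the two-sided
    slope test (F with 1 and nh−2 df).
    """

    indicator_name: str
    stratum: str
    tth: float
    lag: int
    alpha: float
    p0: float
    r2: float
    p_value: float
    n_events: int
    annual_memr: float = float("nan")

    @property
    def significance(self) -> str:
        return significance_tier(self.p_value)


@dataclass(frozen=True)
class GridSpec:
    """Search grid for the (Tth, L) pair and event-extraction settings.

    ``min_events`` is the eligibility floor for a (Tth, L) combination:
    regressions on very few events produce near-unity R² by chance alone,
    so an R²-maximising search over a 450-cell grid is degenerate unless
    sparse combinations are excluded.  Ten events keeps the slope test
    meaningfully powered while still admitting thresholds well above the
    seasonal peak; three is the bare algebraic minimum for a p-value and
    is only sensible when the grid is a single cell.
    """

    thresholds: tuple[float, ...] = tuple(float(t) for t in range(21, 51))
    lags: tuple[int, ...] = tuple(range(0, 15))
    min_events: int = 10
    min_run: int = 3

    def __post_init__(self) -> None:
        if not self.thresholds or not self.lags:
            raise InvalidInputError("threshold and lag grids must be non-empty")
        if self.min_run < 3:
            raise InvalidInputError("events are defined on at least three days")


def extract_events(
    values: np.ndarray | DailyIndicatorSeries,
    tth: float,
    min_run: int = 3,
) -> list[tuple[int, int]]:
    """All maximal runs of ≥ ``min_run`` consecutive days with Tx > Tth.

    Exceedance is strict; days with missing values (NaN) terminate runs.
    Returns ``(start_index, duration)`` pairs in chronological order.
    """
    if isinstance(values, DailyIndicatorSeries):
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("cannot extract events from an empty series")
    exceed = np.where(np.isnan(values), False, values > tth)
    events: list[tuple[int, int]] = []
    run_start = None
    for i, flag in enumerate(exceed):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= min_run:
                events.append((run_start, i - run_start))
            run_start = None
    if run_start is not None and len(exceed) - run_start >= min_run:
        events.append((run_start, len(exceed) - run_start))
    return events


def event_magnitude(tx_window: Sequence[float], tth: float) -> float:
    """Event magnitude Mi = log₁₀(1 + Σ (Tx − Tth)) over the event days."""
    window = np.asarray(tx_window, dtype=float)
    if window.size == 0 or np.any(~np.isfinite(window)):
        raise InvalidInputError("event window must be non-empty and finite")
    excess = window - tth
    if np.any(excess <= 0):
        raise InvalidInputError(
            "all event days must strictly exceed the threshold"
        )
    return float(np.log10(1.0 + excess.sum()))


def assign_lag_windows(
    events: Sequence[tuple[int, int]], lag: int, series_length: int
) -> list[int]:
    """Truncated lag Li for each event.

    Li = min(L, gap to the next event's start, days remaining to the
    series end): lag days overlapping the next event are attributed to
    that event, and windows never extend past the series.
    """
    if lag < 0:
        raise InvalidInputError("lag must be non-negative")
    lags: list[int] = []
    for k, (di, Di) in enumerate(events):
        end = di + Di - 1
        room = series_length - 1 - end
        if k + 1 < len(events):
            next_start = events[k + 1][0]
            room = min(room, next_start - end - 1)
        lags.append(max(0, min(lag, room)))
    return lags


def event_mean_mortality(
    mortality: MortalitySeries, start_index: int, duration: int, lag: int
) -> tuple[float, float]:
    """Event-mean mortality rate p̄i and mean population over Di+Li days.

    Both the sum and the denominator run over the same truncated window of
    ``duration + lag`` days, so days handed to the next event by the
    overlap rule are excluded consistently.
    """
    window = slice(start_index, start_index + duration + lag)
    n_days = duration + lag
    if start_index < 0 or window.stop > len(mortality):
        raise InvalidInputError("event window extends beyond the mortality series")
    rates = mortality.daily_rate()[window]
    if rates.size != n_days or np.any(~np.isfinite(rates)):
        raise InvalidInputError("mortality window contains missing days")
    return float(rates.mean()), float(mortality.population[window].mean())


def fit_event_regression(
    magnitudes: Sequence[float],
    mean_rates: Sequence[float],
    min_events: int = 3,
) -> tuple[float, float, float, float]:
    """Ordinary least squares of event-mean rate on event magnitude.

    Returns ``(alpha, p0, r2, p_value)``.  R² is the squared Pearson
    correlation; the p-value is the two-sided test of zero slope
    (equivalently the regression F-test with 1 and nh−2 df).
    """
    x = np.asarray(magnitudes, dtype=float)
    y = np.asarray(mean_rates, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("magnitudes and rates must have equal length")
    if x.size < min_events:
        raise UnfitTableError(
            f"{x.size} events < minimum {min_events} required for regression"
        )
    if np.ptp(x) == 0:
        raise UnfitTableError("zero variance in event magnitudes")
    result = stats.linregress(x, y)
    return (
        float(result.slope),
        float(result.intercept),
        float(result.rvalue**2),
        float(result.pvalue),
    )


def build_events(
    series: DailyIndicatorSeries,
    mortality: MortalitySeries,
    tth: float,
    lag: int,
    min_run: int = 3,
) -> list[HeatwaveEvent]:
    """Extract events at (Tth, L) and attach magnitudes and mortality."""
    if len(series) != len(mortality):
        raise InvalidInputError("indicator and mortality series must align")
    raw = extract_events(series.values, tth, min_run)
    lags = assign_lag_windows(raw, lag, len(series))
    events: list[HeatwaveEvent] = []
    for (di, Di), li in zip(raw, lags):
        mi = event_magnitude(series.values[di : di + Di], tth)
        p_bar, n_bar = event_mean_mortality(mortality, di, Di, li)
        events.append(
            HeatwaveEvent(
                start_index=di,
                duration=Di,
                lag=li,
                magnitude=mi,
                mean_rate=p_bar,
                mean_population=n_bar,
            )
        )
    return events


def grid_search(
    series: DailyIndicatorSeries,
    mortality: MortalitySeries,
    grid: GridSpec | None = None,
) -> tuple[ModelFit, pd.DataFrame]:
    """Exhaustive search over (Tth, L) maximising R².

    Every grid combination with at least ``grid.min_events`` events is
    fitted; the best fit plus the full diagnostic table are returned.
    Ties in R² break deterministically toward the smaller lag, then the
    larger threshold (parsimony, then event intensity), independent of
    evaluation order.
    """
    grid = grid or GridSpec()
    rows: list[dict] = []
    for tth in grid.thresholds:
        raw = extract_events(series.values, tth, grid.min_run)
        if len(raw) < grid.min_events:
            continue
        magnitudes = np.array(
            [event_magnitude(series.values[di : di + Di], tth) for di, Di in raw]
        )
        for lag in grid.lags:
            lags = assign_lag_windows(raw, lag, len(series))
            try:
                rates = np.array(
                    [
                        event_mean_mortality(mortality, di, Di, li)[0]
                        for (di, Di), li in zip(raw, lags)
                    ]
                )
                alpha, p0, r2, p_value = fit_event_regression(
                    magnitudes, rates, grid.min_events
                )
            except (UnfitTableError, InvalidInputError):
                continue
            rows.append(
                {
                    "tth": tth,
                    "lag": lag,
                    "alpha": alpha,
                    "p0": p0,
                    "r2": r2,
                    "p_value": p_value,
                    "n_events": len(raw),
                }
            )
    if not rows:
        raise NoModelError(
            "no (Tth, L) combination produced enough events to fit a model"
        )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["r2", "lag", "tth"], ascending=[False, True, False], kind="mergesort"
    )
    best = ranked.iloc[0]
    fit = ModelFit(
        indicator_name=series.indicator_name,
        stratum=mortality.stratum,
        tth=float(best["tth"]),
        lag=int(best["lag"]),
        alpha=float(best["alpha"]),
        p0=float(best["p0"]),
        r2=float(best["r2"]),
        p_value=float(best["p_value"]),
        n_events=int(best["n_events"]),
    )
    return fit, table


def significance_tier(p_value: float) -> str:
    """Star convention: *** at the 95% level, ** at 90%, * at 85%, else NS."""
    if not (0.0 <= p_value <= 1.0):
        raise InvalidInputError(f"p-value {p_value} outside [0, 1]")
    if p_value <= 0.05:
        return "***"
    if p_value <= 0.10:
        return "**"
    if p_value <= 0.15:
        return "*"
    return "NS"
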