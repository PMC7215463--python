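"""Model evaluation: predicted event mortality, RMSE/NRMSE, annual MEMR.

The fitted model predicts the total mortality of event *i* as

    N̂death,i = Ni · (Mi·α + p0)·10⁻⁶ · (Di + Li)

i.e. the fitted daily rate (carried in 10⁻⁶·day⁻¹ and converted to a raw
per-person rate) times the person-days of the event-plus-lag window.
Predicted totals are compared with observed window totals via the
root-mean-square error and its normalisation by the mean observed total.
Models are built on training years and scored on held-out years with the
(Tth, L, α, p0) quadruple frozen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .events import (
    GridSpec,
    HeatwaveEvent,
    ModelFit,
    MortalitySeries,
    RATE_SCALE,
    build_events,
    grid_search,
)
from .thermal import DailyIndicatorSeries

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "estimate_event_mortality",
    "rmse",
    "nrmse",
    "annual_memr",
    "observed_event_mortality",
    "evaluate_events",
    "train_test_evaluate",
]


@dataclass(frozen=True)
class EvalResult:
    """Scores for one (indicator, stratum, period).

    ``rmse`` is in deaths; ``nrmse`` is dimensionless
    (RMSE over the mean observed event total).  ``observed`` and
    ``estimated`` keep the per-event totals for diagnostics.
    """

    indicator_name: str
    stratum: str
    period: str  # "train" or "test"
    n_events: int
    rmse: float
    nrmse: float
    observed: tuple[float, ...] = ()
    estimated: tuple[float, ...] = ()

    @property
    def empty(self) -> bool:
        return self.n_events == 0


def estimate_event_mortality(event: HeatwaveEvent, fit: ModelFit) -> float:
    """Predicted total deaths over the event's Di+Li window.

    Uses the event's mean population; may be fractional, and a negative
    prediction (possible when the fitted intercept is negative) is
    returned as-is with a warning so residual diagnostics stay honest.
    """
    rate = (event.magnitude * fit.alpha + fit.p0) * RATE_SCALE
    total = event.mean_population * rate * event.window_days
    if total < 0:
        logger.warning(
            "negative predicted mortality %.3f for event at index %d",
            total,
            event.start_index,
        )
    return float(total)


def observed_event_mortality(mortality: MortalitySeries, event: HeatwaveEvent) -> float:
    """Observed total deaths over the event's Di+Li window."""
    window = slice(event.start_index, event.start_index + event.window_days)
    if window.stop > len(mortality):
        raise InvalidInputError("event window extends beyond the mortality series")
    return float(mortality.deaths[window].sum())


def rmse(observed: Sequence[float], estimated: Sequence[float]) -> float:
    """Root-mean-square error between observed and estimated totals."""
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if obs.size == 0 or obs.shape != est.shape:
        raise InvalidInputError("observed and estimated must be equal-length, non-empty")
    return float(np.sqrt(np.mean((obs - est) ** 2)))


def nrmse(observed: Sequence[float], estimated: Sequence[float]) -> float:
    """RMSE normalised by the mean observed total (relative error).

    Invariant under a common rescaling of both vectors, so models with
    different event counts and population sizes can be compared.
    """
    obs = np.asarray(observed, dtype=float)
    mean_obs = obs.mean() if obs.size else 0.0
    if obs.size == 0 or mean_obs <= 0:
        raise InvalidInputError("mean observed total must be positive")
    return rmse(observed, estimated) / float(mean_obs)


def annual_memr(fit: ModelFit, events: Sequence[HeatwaveEvent], n_years: float) -> float:
    """Annual mean excess mortality rate, 10⁻⁶·year⁻¹.

    Convention: the fitted excess rate α·Mi accrues on every day of event
    i's Di+Li window, so the annual excess per 10⁶ persons is
    Σᵢ α·Mi·(Di+Li) / n_years.
    """
    if n_years <= 0:
        raise InvalidInputError("n_years must be positive")
    total = sum(fit.alpha * e.magnitude * e.window_days for e in events)
    return float(total / n_years)


def evaluate_events(
    mortality: MortalitySeries,
    events: Sequence[HeatwaveEvent],
    fit: ModelFit,
    period: str,
) -> EvalResult:
    """Score a set of events under a (frozen) fit."""
    if not events:
        return EvalResult(fit.indicator_name, mortality.stratum, period, 0,
                          float("nan"), float("nan"))
    observed = tuple(observed_event_mortality(mortality, e) for e in events)
    estimated = tuple(estimate_event_mortality(e, fit) for e in events)
    return EvalResult(
        indicator_name=fit.indicator_name,
        stratum=mortality.stratum,
        period=period,
        n_events=len(events),
        rmse=rmse(observed, estimated),
        nrmse=nrmse(observed, estimated),
        observed=observed,
        estimated=estimated,
    )


def _slice_series(
    series: DailyIndicatorSeries, mortality: MortalitySeries, mask: np.ndarray
) -> tuple[DailyIndicatorSeries, MortalitySeries]:
    idx = np.flatnonzero(mask)
    sub_dates = tuple(series.dates[i] for i in idx)
    return (
        DailyIndicatorSeries(sub_dates, series.values[idx], series.indicator_name),
        MortalitySeries(
            sub_dates,
            mortality.deaths[idx],
            mortality.population[idx],
            mortality.region,
            mortality.age_group,
        ),
    )


def train_test_evaluate(
    series: DailyIndicatorSeries,
    mortality: MortalitySeries,
    grid: GridSpec | None = None,
    split_year: int | None = None,
) -> dict:
    """Fit on years ≤ ``split_year``, score train and held-out years.

    The model (Tth, L, α, p0) is selected by grid search on the training
    years only; test events are extracted with the frozen Tth and L and
    scored with the frozen coefficients.  A test period without events
    yields an empty (flagged) result, not an error.

    Returns ``{"fit": ModelFit, "table": DataFrame, "train": EvalResult,
    "test": EvalResult}``.
    """
    years = np.array([d.year for d in series.dates])
    if split_year is None:
        split_year = int(years.max())  # no held-out period
    if split_year < years.min():
        raise InvalidInputError("split year precedes the data span")
    train_mask = years <= split_year
    test_mask = ~train_mask

    train_series, train_mort = _slice_series(series, mortality, train_mask)
    fit, table = grid_search(train_series, train_mort, grid)
    grid = grid or GridSpec()

    train_events = build_events(
        train_series, train_mort, fit.tth, fit.lag, grid.min_run
    )
    n_train_years = len(np.unique(years[train_mask]))
    fit = ModelFit(
        **{
            **fit.__dict__,
            "annual_memr": annual_memr(fit, train_events, n_train_years),
        }
    )
    train_result = evaluate_events(train_mort, train_events, fit, "train")

    if test_mask.any():
        test_series, test_mort = _slice_series(series, mortality, test_mask)
        test_events = build_events(
            test_series, test_mort, fit.tth, fit.lag, grid.min_run
        )
        test_result = evaluate_events(test_mort, test_events, fit, "test")
    else:
        test_result = EvalResult(
            fit.indicator_name, mortality.stratum, "test", 0, float("nan"), float("nan")
        )

    return {"fit": fit, "table": table, "train": train_result, "test": test_result}


def eval_results_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Tabulate evaluation results (`indicator,stratum,period,n_events,rmse,nrmse`)."""
    return pd.DataFrame(
        {
            "indicator": [r.indicator_name for r in results],
            "stratum": [r.stratum for r in results],
            "period": [r.period for r in results],
            "n_events": [r.n_events for r in results],
            "rmse": [r.rmse for r in results],
            "nrmse": [r.nrmse for r in results],
        }
    )
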