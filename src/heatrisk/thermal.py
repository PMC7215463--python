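"""Thermal-comfort temperature indicators.

Computes the three indicators used by the event-based heat-risk pipeline
from hourly meteorology:

* **Ta** — dry-bulb air temperature (identity indicator).
* **WBGT** — wet-bulb globe temperature, estimated from air temperature and
  the Stull wet-bulb approximation through the empirical two-variable
  polynomial calibrated by the Korea Meteorological Administration (KMA).
* **PT** — perceived temperature: the air temperature of a reference
  environment producing the same thermal perception as the actual
  conditions.  On the heat branch it is an affine translation of the
  predicted mean vote (PMV), which is itself a scaled thermal load from a
  Fanger-style steady-state heat balance of a walking reference person.

Hourly indicator values are reduced to daily maxima (``daily_max``), the
exposure series the event model consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, NumericalFailureError, OutOfBranchError

logger = logging.getLogger(__name__)

__all__ = [
    "MetRecord",
    "ReferencePerson",
    "HeatBudgetTerms",
    "DailyIndicatorSeries",
    "stull_wet_bulb",
    "kma_wbgt",
    "reference_wbgt",
    "pmv_scale_factor",
    "thermal_load",
    "compute_pmv",
    "pt_from_pmv",
    "estimate_mrt",
    "daily_max",
    "read_hourly_met_csv",
]

#: Boltzmann radiation constant used in the clothing-surface balance,
#: W·m⁻²·K⁻⁴ scaled by (T/100)⁴ bookkeeping.
_RAD = 3.96

#: PT translation on the heat branch: PT = _PT_SLOPE·PMV + _PT_INTERCEPT.
_PT_SLOPE = 6.18
_PT_INTERCEPT = 16.83


@dataclass(frozen=True)
class MetRecord:
    """One hourly meteorological observation.

    Parameters
    ----------
    timestamp : datetime
        Local civil time of the observation (hourly cadence expected).
    ta : float
        Air temperature, °C.
    rh : float
        Relative humidity, % in [0, 100].
    td : float, optional
        Dew-point temperature, °C; must not exceed ``ta`` when present.
    wind : float
        Wind speed, m·s⁻¹, non-negative.
    cloud_amount : float, optional
        Total cloud cover normalised to [0, 1].
    tmrt : float, optional
        Mean radiant temperature, °C.  When present it overrides any
        internal estimate.
    """

    timestamp: datetime
    ta: float
    rh: float
    wind: float = 0.0
    td: float | None = None
    cloud_amount: float | None = None
    tmrt: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rh <= 100.0):
            raise InvalidInputError(f"relative humidity {self.rh} outside [0, 100] %")
        if self.wind < 0:
            raise InvalidInputError(f"wind speed {self.wind} m/s is negative")
        if self.td is not None and self.ta is not None and self.td > self.ta + 1e-9:
            raise InvalidInputError(
                f"dew point {self.td} °C exceeds air temperature {self.ta} °C"
            )
        if self.cloud_amount is not None and not (0.0 <= self.cloud_amount <= 1.0):
            raise InvalidInputError(
                f"cloud amount {self.cloud_amount} outside [0, 1]"
            )


@dataclass(frozen=True)
class ReferencePerson:
    """Reference subject for the PMV heat balance.

    The default is the walking adult used for perceived-temperature work:
    35 years, 1.75 m, 75 kg, summer clothing (0.5 clo), walking at 4 km/h
    (1.11 m·s⁻¹) on flat ground, metabolic rate 135 W·m⁻², no external
    mechanical work.
    """

    age: float = 35.0
    height_m: float = 1.75
    weight_kg: float = 75.0
    metabolic_rate: float = 135.0  # M, W·m⁻²
    external_work: float = 0.0  # W, W·m⁻²
    clothing_clo: float = 0.5
    walking_speed: float = 1.11  # m·s⁻¹

    def __post_init__(self) -> None:
        if self.metabolic_rate <= 0:
            raise InvalidInputError("metabolic rate must be positive")
        if self.clothing_clo < 0 or self.external_work < 0:
            raise InvalidInputError("clothing and external work must be non-negative")


@dataclass(frozen=True)
class HeatBudgetTerms:
    """Components of the steady-state human heat balance, all in W·m⁻².

    Under the steady-state contract the storage terms are zero and the
    thermal load is ``Lth = M − W − (Cskin + Rskin + Eskin) − (Cres + Eres)``.
    """

    Cskin: float
    Rskin: float
    Eskin: float
    Cres: float
    Eres: float
    Sskin: float = 0.0
    Score: float = 0.0
    Lth: float = field(default=float("nan"))


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if value is None or not math.isfinite(value):
            raise InvalidInputError(f"{name} must be finite, got {value!r}")


def stull_wet_bulb(ta: float, rh: float) -> float:
    """Wet-bulb temperature (°C) from the Stull arctangent approximation.

    Parameters are air temperature ``ta`` in °C and relative humidity
    ``rh`` in %.  All arctangents are evaluated in radians.  The formula
    was fitted for roughly ``ta`` in [−20, 50] °C and ``rh`` in [5, 99] %
    at standard pressure; values outside that envelope are returned
    without adjustment (caveat emptor).
    """
    _require_finite(ta=ta, rh=rh)
    if rh <= 0:
        raise InvalidInputError(f"relative humidity must be positive, got {rh}")
    return (
        ta * math.atan(0.151977 * math.sqrt(rh + 8.313659))
        + math.atan(ta + rh)
        - math.atan(rh - 1.67633)
        + 0.00391838 * rh ** 1.5 * math.atan(0.023101 * rh)
        - 4.686035
    )


def kma_wbgt(tw: float, ta: float) -> float:
    """Empirical Korean WBGT estimate (°C) from wet-bulb and air temperature.

    Quadratic regression calibrated by the KMA against reference WBGT
    observations; requires only ``tw`` and ``ta`` (no black-globe input).
    """
    _require_finite(tw=tw, ta=ta)
    return (
        -0.2442
        + 0.55399 * tw
        + 0.45535 * ta
        - 0.0022 * tw * tw
        + 0.00278 * tw * ta
    )


def reference_wbgt(tw: float, tg: float, ta: float) -> float:
    """Instrumental (outdoor, sun-exposed) WBGT definition.

    Weighted average ``0.7·Tw + 0.2·Tg + 0.1·Ta`` of natural wet-bulb,
    black-globe and air temperature.  Provided for cross-checks; the
    pipeline uses :func:`kma_wbgt` because black-globe temperature is not
    a standard station element.
    """
    _require_finite(tw=tw, tg=tg, ta=ta)
    return 0.7 * tw + 0.2 * tg + 0.1 * ta


def pmv_scale_factor(metabolic_rate: float) -> float:
    """Sensitivity coefficient mapping thermal load (W·m⁻²) to PMV units.

    ``0.303·exp(−0.036·M) + 0.0275``; strictly decreasing in the metabolic
    rate M with infimum 0.0275.
    """
    if metabolic_rate is None or not math.isfinite(metabolic_rate) or metabolic_rate < 0:
        raise InvalidInputError(f"metabolic rate must be a finite non-negative number, got {metabolic_rate!r}")
    return 0.303 * math.exp(-0.036 * metabolic_rate) + 0.0275


def _saturation_vapor_pressure_pa(ta: float) -> float:
    # Antoine-style fit used throughout comfort modelling; Pa at air temp °C.
    return 1000.0 * math.exp(16.6536 - 4030.183 / (ta + 235.0))


def _solve_clothing_temperature(
    ta: float,
    tr: float,
    var: float,
    icl: float,
    fcl: float,
    mw: float,
    tol: float = 1e-4,
    max_iter: int = 150,
) -> tuple[float, float]:
    """Damped fixed-point iteration for the clothing-surface temperature.

    Returns ``(tcl, hc)`` in (°C, W·m⁻²·K⁻¹).  ``tol`` is the convergence
    tolerance on the surface temperature in °C.
    """
    taa = ta + 273.0
    tra = tr + 273.0
    tcla = taa + (35.5 - ta) / (3.5 * icl + 0.1)

    p1 = icl * fcl
    p2 = p1 * _RAD
    p3 = p1 * 100.0
    p4 = p1 * taa
    p5 = 308.7 - 0.028 * mw + p2 * (tra / 100.0) ** 4

    hcf = 12.1 * math.sqrt(max(var, 0.0))
    xn = tcla / 100.0
    xf = xn
    hc = hcf
    for iteration in range(1, max_iter + 1):
        xf = (xf + xn) / 2.0  # damping: average of the last two iterates
        hcn = 2.38 * abs(100.0 * xf - taa) ** 0.25
        hc = max(hcf, hcn)
        xn = (p5 + p4 * hc - p2 * xf ** 4) / (100.0 + p3 * hc)
        if abs(xn - xf) * 100.0 < tol:
            return 100.0 * xn - 273.0, hc
    raise NumericalFailureError(
        "clothing-surface temperature iteration did not converge",
        iterations=max_iter,
        residual=abs(xn - xf) * 100.0,
    )


def thermal_load(
    ta: float,
    tr: float,
    rh: float,
    var: float,
    person: ReferencePerson,
) -> HeatBudgetTerms:
    """Steady-state thermal load of the reference person.

    Evaluates the Fanger heat balance: convective and radiative exchange
    at the clothing surface, evaporative heat loss from the skin
    (diffusion plus regulatory sweating above sedentary activity), and
    respiratory latent and dry heat loss.  ``var`` is the air speed
    relative to the body, m·s⁻¹.

    Returns the individual terms; ``Lth`` is the residual of metabolic
    heat production over total loss.
    """
    _require_finite(ta=ta, tr=tr, rh=rh, var=var)
    m = person.metabolic_rate
    w = person.external_work
    mw = m - w
    pa = rh / 100.0 * _saturation_vapor_pressure_pa(ta)

    icl = 0.155 * person.clothing_clo
    fcl = 1.0 + 1.29 * icl if icl <= 0.078 else 1.05 + 0.645 * icl

    tcl, hc = _solve_clothing_temperature(ta, tr, var, icl, fcl, mw)

    # skin terms
    e_diffusion = 3.05e-3 * (5733.0 - 6.99 * mw - pa)
    e_sweat = 0.42 * (mw - 58.15) if mw > 58.15 else 0.0
    e_skin = e_diffusion + e_sweat
    r_skin = _RAD * fcl * (((tcl + 273.0) / 100.0) ** 4 - ((tr + 273.0) / 100.0) ** 4)
    c_skin = fcl * hc * (tcl - ta)
    # respiratory terms
    e_res = 1.7e-5 * m * (5867.0 - pa)
    c_res = 0.0014 * m * (34.0 - ta)

    lth = mw - (c_skin + r_skin + e_skin) - (c_res + e_res)
    return HeatBudgetTerms(
        Cskin=c_skin, Rskin=r_skin, Eskin=e_skin, Cres=c_res, Eres=e_res, Lth=lth
    )


def compute_pmv(met: MetRecord, person: ReferencePerson | None = None) -> float:
    """Predicted mean vote for one meteorological record.

    ``PMV = α(M) · Lth`` with the scale factor from
    :func:`pmv_scale_factor` and the thermal load from
    :func:`thermal_load`.  The mean radiant temperature is taken from
    ``met.tmrt`` when present, otherwise it falls back to the air
    temperature (use :func:`estimate_mrt` to fill it beforehand when a
    radiation estimate is wanted).  The air speed relative to the walking
    body is the wind speed plus the walking speed.
    """
    person = person or ReferencePerson()
    tr = met.tmrt if met.tmrt is not None else met.ta
    var = met.wind + person.walking_speed
    terms = thermal_load(met.ta, tr, met.rh, var, person)
    return pmv_scale_factor(person.metabolic_rate) * terms.Lth


def pt_from_pmv(pmv: float) -> float:
    """Perceived temperature (°C) on the heat branch.

    ``PT = 6.18·PMV + 16.83`` for PMV ≥ 0.  The branch boundary PMV = 0
    is accepted (returning 16.83) so the translation is continuous there;
    negative PMV belongs to the cold branch, which uses different
    formulas and is out of scope here.
    """
    _require_finite(pmv=pmv)
    if pmv < 0:
        raise OutOfBranchError(
            f"PMV={pmv} is on the cold branch; the heat-branch translation "
            "requires PMV >= 0"
        )
    return _PT_SLOPE * pmv + _PT_INTERCEPT


# ---------------------------------------------------------------------------
# Mean radiant temperature estimation
# ---------------------------------------------------------------------------


def _solar_elevation_deg(when: datetime, lat: float, lon: float) -> float:
    """Solar elevation above the horizon, degrees.

    Low-precision ephemeris (declination from day-of-year, hour angle from
    local civil time corrected by longitude offset within the time zone is
    ignored); adequate for day/night and rough-noon discrimination.
    """
    doy = when.timetuple().tm_yday
    decl = -23.44 * math.cos(math.radians(360.0 / 365.0 * (doy + 10)))
    hour = when.hour + when.minute / 60.0
    hour_angle = 15.0 * (hour - 12.0)
    lat_r = math.radians(lat)
    decl_r = math.radians(decl)
    ha_r = math.radians(hour_angle)
    sin_el = math.sin(lat_r) * math.sin(decl_r) + math.cos(lat_r) * math.cos(
        decl_r
    ) * math.cos(ha_r)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_el))))


def estimate_mrt(
    met: MetRecord,
    lat: float,
    lon: float = 0.0,
    elevation_m: float = 0.0,
    max_clear_sky_gain: float = 20.0,
) -> float:
    """Estimate the mean radiant temperature (°C) for one record.

    Simplified clear-sky shortwave model: under sun, the radiant
    temperature exceeds the air temperature by a gain proportional to the
    sine of the solar elevation, attenuated by cloud cover
    (``1 − cloud³``, a standard global-radiation cloud correction).  At
    night or under full overcast the estimate collapses to
    ``Tmrt = Ta``.  When cloud information is missing the fallback
    ``Tmrt = Ta`` is used and a warning logged.

    ``max_clear_sky_gain`` is the Tmrt − Ta excess (°C) for a sun-exposed
    person at solar elevation 90° under a cloudless sky; the default 20 °C
    is typical of mid-latitude summer field measurements.
    """
    if met.tmrt is not None:
        return met.tmrt
    if met.cloud_amount is None:
        logger.warning(
            "no cloud information at %s; falling back to Tmrt = Ta", met.timestamp
        )
        return met.ta
    elevation = _solar_elevation_deg(met.timestamp, lat, lon)
    if elevation <= 0:
        return met.ta
    attenuation = 1.0 - met.cloud_amount ** 3
    gain = max_clear_sky_gain * math.sin(math.radians(elevation)) * attenuation
    return met.ta + gain


# ---------------------------------------------------------------------------
# Daily reduction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DailyIndicatorSeries:
    """Per-day maxima of one temperature indicator.

    ``dates`` are consecutive calendar days; ``values`` holds one °C value
    per day with NaN marking a day that failed the completeness screen.
    """

    dates: tuple[date, ...]
    values: np.ndarray  # float array, NaN = missing
    indicator_name: str = "Tmax"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.dates) != len(values):
            raise InvalidInputError("dates and values must have equal length")
        for prev, nxt in zip(self.dates, self.dates[1:]):
            if (nxt - prev).days != 1:
                raise InvalidInputError(
                    f"dates must increase by exactly one day ({prev} -> {nxt})"
                )
        finite = values[~np.isnan(values)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise InvalidInputError("values must be finite or NaN")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": pd.to_datetime(list(self.dates)),
                "indicator": self.indicator_name,
                "value": self.values,
            }
        )


def daily_max(
    timestamps: Sequence[datetime],
    values: Sequence[float],
    indicator_name: str = "Tmax",
    min_valid_hours: int = 18,
) -> DailyIndicatorSeries:
    """Reduce hourly indicator values to per-day maxima.

    A calendar day with fewer than ``min_valid_hours`` finite hourly
    values is marked missing (NaN): sparse days would otherwise report
    spurious maxima.  Days between the first and last observed day that
    have no data at all are likewise missing.  Input order is irrelevant.
    """
    if len(timestamps) == 0:
        raise InvalidInputError("daily_max requires at least one observation")
    if len(timestamps) != len(values):
        raise InvalidInputError("timestamps and values must have equal length")
    frame = pd.DataFrame({"ts": pd.to_datetime(list(timestamps)), "value": list(values)})
    frame["day"] = frame["ts"].dt.date
    grouped = frame.groupby("day")["value"]
    counts = grouped.apply(lambda s: int(np.isfinite(s.to_numpy(dtype=float)).sum()))
    maxima = grouped.max()

    first, last = min(counts.index), max(counts.index)
    days = pd.date_range(first, last, freq="D").date
    out = np.full(len(days), np.nan)
    for i, day in enumerate(days):
        if day in counts.index and counts[day] >= min_valid_hours:
            out[i] = maxima[day]
    return DailyIndicatorSeries(tuple(days), out, indicator_name=indicator_name)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_hourly_met_csv(path) -> list[MetRecord]:
    """Read hourly meteorology from CSV.

    Expected columns: ``timestamp,ta,rh,td,wind,cloud,tmrt`` with ISO-8601
    timestamps; empty cells are missing.  Rows violating the physical
    ranges (RH outside [0, 100], negative wind, dew point above air
    temperature) are rejected with a logged warning rather than raising,
    so one bad row does not abort a station file.
    """
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    records: list[MetRecord] = []
    for row in frame.itertuples(index=False):
        def _opt(name: str) -> float | None:
            value = getattr(row, name, None)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            return float(value)

        try:
            records.append(
                MetRecord(
                    timestamp=row.timestamp.to_pydatetime(),
                    ta=float(row.ta),
                    rh=float(row.rh),
                    wind=_opt("wind") or 0.0,
                    td=_opt("td"),
                    cloud_amount=_opt("cloud"),
                    tmrt=_opt("tmrt"),
                )
            )
        except (InvalidInputError, TypeError, ValueError) as exc:
            logger.warning("rejecting met row at %s: %s", row.timestamp, exc)
    return records


def hourly_indicator(
    records: Iterable[MetRecord],
    indicator: str,
    person: ReferencePerson | None = None,
) -> tuple[list[datetime], list[float]]:
    """Evaluate one indicator over a stream of hourly records.

    ``indicator`` is one of ``"Ta"``, ``"WBGT"``, ``"PT"``.  PT values on
    the cold branch (PMV < 0) are reported as NaN: the heat-branch
    translation does not apply there, and for daily *maxima* in the warm
    season those hours never win.
    """
    timestamps: list[datetime] = []
    values: list[float] = []
    for met in records:
        timestamps.append(met.timestamp)
        if indicator == "Ta":
            values.append(met.ta)
        elif indicator == "WBGT":
            values.append(kma_wbgt(stull_wet_bulb(met.ta, max(met.rh, 1e-9)), met.ta))
        elif indicator == "PT":
            pmv = compute_pmv(met, person)
            values.append(pt_from_pmv(pmv) if pmv >= 0 else float("nan"))
        else:
            raise InvalidInputError(f"unknown indicator {indicator!r}")
    return timestamps, values
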