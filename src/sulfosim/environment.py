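"""Environmental drivers: weather series, thermal time, canopy light capture.

The simulator is driven by three daily inputs — minimum and maximum air
temperature and incident photosynthetically active radiation (PAR) above the
canopy.  This module owns the weather record container, the degree-day clock
(mean temperature above a 5 °C base) and Beer–Monteith light interception,
which converts incident PAR and leaf area index into absorbed PAR.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WeatherRecord",
    "InvalidWeatherError",
    "daily_thermal_time",
    "par_absorbed",
    "cumulative_thermal_time",
    "read_weather_csv",
    "write_weather_csv",
    "constant_weather",
]

WEATHER_COLUMNS = ("day", "tmin", "tmax", "par")


class InvalidWeatherError(ValueError):
    """Raised for weather records that violate basic physical constraints."""


@dataclass(frozen=True)
class WeatherRecord:
    """One day of environmental drivers.

    Parameters
    ----------
    day_index : int
        Ordinal day within the series (strictly increasing).
    t_min, t_max : float
        Daily minimum / maximum air temperature, °C.
    par_incident : float
        Incident PAR above the canopy, MJ m⁻² d⁻¹.
    """

    day_index: int
    t_min: float
    t_max: float
    par_incident: float

    def __post_init__(self) -> None:
        for name in ("t_min", "t_max", "par_incident"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidWeatherError(
                    f"day {self.day_index}: non-finite {name} ({v!r})"
                )
        if self.t_max < self.t_min:
            raise InvalidWeatherError(
                f"day {self.day_index}: t_max ({self.t_max}) < t_min ({self.t_min})"
            )
        if self.par_incident < 0:
            raise InvalidWeatherError(
                f"day {self.day_index}: negative PAR ({self.par_incident})"
            )


def daily_thermal_time(t_min: float, t_max: float, t_base: float = 5.0) -> float:
    """Daily thermal-time increment, °Cd.

    The daily mean temperature (arithmetic mean of the min/max probes) above
    the base temperature, clamped at zero: cold days add no development.
    """
    if t_max < t_min:
        raise InvalidWeatherError(f"t_max ({t_max}) < t_min ({t_min})")
    return max(0.0, 0.5 * (t_min + t_max) - t_base)


def par_absorbed(par_incident: float, lai: float, k: float) -> float:
    """PAR absorbed by the canopy (MJ m⁻²), Beer's-law exponential closure.

    ``par_incident * (1 - exp(-k * lai))`` with *lai* the big-leaf leaf area
    index (m² leaf per m² ground) and *k* the extinction coefficient.
    """
    if lai < 0:
        raise ValueError(f"negative LAI ({lai})")
    if k <= 0:
        raise ValueError(f"extinction coefficient must be positive (got {k})")
    if par_incident < 0:
        raise ValueError(f"negative incident PAR ({par_incident})")
    return par_incident * -math.expm1(-k * lai)


def cumulative_thermal_time(
    records: Sequence[WeatherRecord], t_base: float = 5.0
) -> np.ndarray:
    """Accumulated thermal time after each day of the series, °Cd."""
    increments = [daily_thermal_time(r.t_min, r.t_max, t_base) for r in records]
    return np.cumsum(increments)


def constant_weather(
    n_days: int, t_min: float = 10.0, t_max: float = 20.0, par: float = 5.0
) -> list[WeatherRecord]:
    """A constant synthetic series — the standard deterministic test driver."""
    return [WeatherRecord(i, t_min, t_max, par) for i in range(1, n_days + 1)]


def read_weather_csv(path: str | Path) -> list[WeatherRecord]:
    """Read a weather series from CSV with header ``day,tmin,tmax,par``.

    Missing or non-numeric cells are errors; no imputation is attempted.
    """
    path = Path(path)
    records: list[WeatherRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise InvalidWeatherError(f"{path}: empty weather file") from None
        if tuple(h.strip().lower() for h in header) != WEATHER_COLUMNS:
            raise InvalidWeatherError(
                f"{path}: expected header {','.join(WEATHER_COLUMNS)!r}, "
                f"got {','.join(header)!r}"
            )
        last_day = None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4 or any(not c.strip() for c in row):
                raise InvalidWeatherError(
                    f"{path}:{lineno}: expected 4 non-empty fields, got {row!r}"
                )
            try:
                day = int(row[0])
                tmin, tmax, par = (float(c) for c in row[1:])
            except ValueError as exc:
                raise InvalidWeatherError(f"{path}:{lineno}: {exc}") from None
            if last_day is not None and day <= last_day:
                raise InvalidWeatherError(
                    f"{path}:{lineno}: day index {day} not strictly increasing"
                )
            last_day = day
            records.append(WeatherRecord(day, tmin, tmax, par))
    if not records:
        raise InvalidWeatherError(f"{path}: weather file has no data rows")
    return records


def write_weather_csv(records: Iterable[WeatherRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(WEATHER_COLUMNS)
        for r in records:
            writer.writerow([r.day_index, repr(r.t_min), repr(r.t_max), repr(r.par_incident)])
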