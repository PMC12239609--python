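"""Temperature response functions and thermal-time accumulation.

Crop development is paced by temperature.  Calendar durations observed in
field trials are converted to thermal time (degree-days, °Cd) by applying a
temperature response function to the daily mean temperature and summing the
resulting daily increments.  Two response kinds are provided:

``linear``
    Classic growing degree days with an optimum cutoff:
    increment = max(0, min(T, t_opt) - t_min), and 0 above ``t_max``.

``beta``
    The Wang–Engel beta response, a smooth unimodal curve rising from the
    base temperature to 1 at the optimum and falling to 0 at the ceiling:

        f(T) = [2 (T-Tmin)^a (Topt-Tmin)^a - (T-Tmin)^(2a)] / (Topt-Tmin)^(2a)

    with shape exponent a = ln 2 / ln((Tmax-Tmin)/(Topt-Tmin)).  The daily
    increment is f(T) * t_scale so that beta-based durations are expressed
    on a °Cd-equivalent scale comparable to linear degree days.

Default cardinal temperatures (8, 30, 43 °C) are typical values for maize;
all are configurable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InsufficientWeatherError, SchemaError

__all__ = [
    "CardinalTemps",
    "WeatherSeries",
    "temp_response",
    "daily_increment",
    "accumulate",
    "date_at_threshold",
    "nrmse_per_genotype",
]


@dataclass(frozen=True)
class CardinalTemps:
    """Cardinal temperatures and response kind for thermal-time calculation.

    Parameters
    ----------
    t_min, t_opt, t_max : float
        Base, optimum and ceiling temperatures in °C; must be strictly
        increasing.
    kind : {"linear", "beta"}
        Response function family.
    t_scale : float, optional
        Scaling span (°C) converting the normalized beta response to a
        °Cd-equivalent daily increment.  Defaults to ``t_opt - t_min``.
    """

    t_min: float = 8.0
    t_opt: float = 30.0
    t_max: float = 43.0
    kind: str = "beta"
    t_scale: float | None = None

    def __post_init__(self):
        if not (self.t_min < self.t_opt < self.t_max):
            raise ConfigurationError(
                f"cardinal temperatures must satisfy t_min < t_opt < t_max, "
                f"got ({self.t_min}, {self.t_opt}, {self.t_max})"
            )
        if self.kind not in ("linear", "beta"):
            raise ConfigurationError(f"unknown response kind {self.kind!r}")
        if self.t_scale is None:
            object.__setattr__(self, "t_scale", self.t_opt - self.t_min)
        elif self.t_scale <= 0:
            raise ConfigurationError("t_scale must be positive")

    @property
    def beta_exponent(self) -> float:
        """Shape exponent a = ln2 / ln((Tmax-Tmin)/(Topt-Tmin))."""
        return np.log(2.0) / np.log((self.t_max - self.t_min) / (self.t_opt - self.t_min))


def temp_response(t, cardinals: CardinalTemps):
    """Normalized temperature response in [0, 1].

    For the beta kind this is the Wang–Engel curve (1 only at ``t_opt``);
    for the linear kind it is the degree-day ramp normalized by
    ``t_opt - t_min`` with a hard cutoff (0) above ``t_max``.

    Accepts scalars or arrays; returns the same shape.
    """
    t = np.asarray(t, dtype=float)
    tmin, topt, tmax = cardinals.t_min, cardinals.t_opt, cardinals.t_max
    if cardinals.kind == "linear":
        r = np.clip((np.minimum(t, topt) - tmin) / (topt - tmin), 0.0, 1.0)
        r = np.where(t > tmax, 0.0, r)
    else:
        a = cardinals.beta_exponent
        with np.errstate(invalid="ignore"):
            x = np.clip(t - tmin, 0.0, None)
            span = topt - tmin
            r = (2.0 * x**a * span**a - x ** (2 * a)) / span ** (2 * a)
        r = np.where((t <= tmin) | (t >= tmax), 0.0, r)
        r = np.clip(r, 0.0, 1.0)
    return r if r.ndim else float(r)


def daily_increment(tmean, cardinals: CardinalTemps):
    """Thermal-time increment (°Cd) for one day at mean temperature ``tmean``.

    Linear kind: classic GDD with optimum cutoff, max(0, min(T, t_opt) - t_min)
    (zero above the ceiling).  Beta kind: f(T) * t_scale.
    """
    tmean = np.asarray(tmean, dtype=float)
    if cardinals.kind == "linear":
        inc = np.clip(np.minimum(tmean, cardinals.t_opt) - cardinals.t_min, 0.0, None)
        inc = np.where(tmean > cardinals.t_max, 0.0, inc)
    else:
        inc = np.asarray(temp_response(tmean, cardinals)) * cardinals.t_scale
    return inc if inc.ndim else float(inc)


class WeatherSeries:
    """Daily weather record for one environment.

    Wraps a DataFrame indexed by calendar date with columns ``tmin``,
    ``tmax`` and ``tmean`` (°C at 2 m).  A missing ``tmean`` is filled with
    (tmin + tmax) / 2.  Dates must be strictly increasing and gap-free;
    tmin <= tmean <= tmax must hold on every row.
    """

    def __init__(self, frame: pd.DataFrame, name: str | None = None):
        if frame.empty:
            raise SchemaError("weather series is empty")
        df = frame.copy()
        if not isinstance(df.index, pd.DatetimeIndex):
            if "date" not in df.columns:
                raise SchemaError("weather frame needs a DatetimeIndex or a 'date' column")
            df.index = pd.DatetimeIndex(pd.to_datetime(df.pop("date")))
        df.index = df.index.normalize()
        for col in ("tmin", "tmax"):
            if col not in df.columns:
                raise SchemaError(f"weather frame missing required column {col!r}")
            df[col] = pd.to_numeric(df[col])
        if "tmean" not in df.columns or df["tmean"].isna().all():
            df["tmean"] = (df["tmin"] + df["tmax"]) / 2.0
        else:
            df["tmean"] = pd.to_numeric(df["tmean"]).fillna((df["tmin"] + df["tmax"]) / 2.0)
        if df[["tmin", "tmax", "tmean"]].isna().any().any():
            bad = int(df[["tmin", "tmax", "tmean"]].isna().any(axis=1).idxmax().day)
            raise SchemaError("weather series contains missing temperatures")
        diffs = np.diff(df.index.values).astype("timedelta64[D]").astype(int)
        if (diffs <= 0).any():
            raise SchemaError(f"weather dates not strictly increasing in series {name!r}")
        if (diffs != 1).any():
            first_gap = df.index[int(np.argmax(diffs != 1))].date()
            raise SchemaError(
                f"weather series {name!r} has a gap after {first_gap} (gaps are an error)"
            )
        bad = (df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])
        if bad.any():
            d = df.index[bad.values][0].date()
            raise SchemaError(f"tmin <= tmean <= tmax violated on {d} in series {name!r}")
        self.frame = df
        self.name = name

    @property
    def start(self) -> dt.date:
        return self.frame.index[0].date()

    @property
    def end(self) -> dt.date:
        return self.frame.index[-1].date()

    def covers(self, date: dt.date) -> bool:
        return self.start <= date <= self.end

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return f"WeatherSeries({self.name!r}, {self.start}..{self.end}, n={len(self)})"


def accumulate(series: WeatherSeries, start: dt.date, cardinals: CardinalTemps) -> pd.Series:
    """Cumulative thermal time (°Cd) from ``start`` (inclusive) to series end.

    The returned Series is indexed by date and non-decreasing; its value on
    ``start`` is that day's own increment.
    """
    start_ts = pd.Timestamp(start)
    if not series.covers(start_ts.date()):
        raise InsufficientWeatherError(
            f"start date {start} outside weather record {series.start}..{series.end}"
            + (f" for environment {series.name}" if series.name else ""),
            env_id=series.name,
        )
    sub = series.frame.loc[start_ts:]
    inc = daily_increment(sub["tmean"].to_numpy(), cardinals)
    return pd.Series(np.cumsum(inc), index=sub.index, name="tt_cd")


def date_at_threshold(
    series: WeatherSeries, start: dt.date, threshold: float, cardinals: CardinalTemps
) -> dt.date:
    """First date, accumulating from ``start``, on which cumulative thermal
    time reaches ``threshold`` °Cd.

    A threshold of 0 returns ``start``.  Raises
    :class:`InsufficientWeatherError` (carrying the remaining shortfall in
    °Cd) if the record ends first.
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    if threshold == 0:
        return pd.Timestamp(start).date()
    cum = accumulate(series, start, cardinals)
    reached = cum.to_numpy() >= threshold
    if not reached.any():
        shortfall = float(threshold - cum.iloc[-1])
        raise InsufficientWeatherError(
            f"insufficient weather record"
            + (f" for environment {series.name}" if series.name else "")
            + f": {shortfall:.1f} °Cd short of {threshold:.1f} °Cd at {series.end}",
            env_id=series.name,
            shortfall=shortfall,
        )
    return cum.index[int(np.argmax(reached))].date()


def nrmse_per_genotype(values) -> float:
    """Range-normalized RMSE of one genotype's thermal times across environments.

    RMSE about the across-environment mean, divided by (max - min).  Used to
    rank temperature response functions: for a photoperiod-insensitive
    genotype the best function yields the most consistent thermal time to
    anthesis across environments, i.e. the smallest value.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 3:
        raise ConfigurationError("need at least 3 values to compute NRMSE")
    rng = v.max() - v.min()
    if rng <= 0:
        raise ConfigurationError("NRMSE undefined for constant values (max == min)")
    rmse = float(np.sqrt(np.mean((v - v.mean()) ** 2)))
    return rmse / rng
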