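"""Envirotyping the sensed daylength (DLs) per environment.

For a genotype (or reference maturity class) with basic vegetative phase
BVP, the sensitization date in an environment is the first calendar day on
which cumulative thermal time from emergence reaches the BVP.  The daylength
on that day — the sensed daylength DLs — is the photoperiod the genotype
actually perceives when it becomes competent to respond, and serves as the
environmental axis of the flowering-time reaction norm.  Because genotypes
differ in phyllochron and leaf number, different genotypes in the same field
can be sensitized on different days and hence sense different photoperiods,
increasingly so at high latitude where daily photoperiodic change is fast.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bvp import REFERENCE_BVP_CD, GenotypeDev, MaturityReference, predict_bvp
from .daylength import DaylengthParams, cbm_daylength, photoperiod_change_rate
from .exceptions import ConfigurationError, InsufficientWeatherError
from .thermal_time import (
    CardinalTemps,
    WeatherSeries,
    accumulate,
    date_at_threshold,
)

log = logging.getLogger(__name__)

__all__ = [
    "Environment",
    "EnvirotypeRecord",
    "predict_emergence",
    "sensed_daylength",
    "intra_env_spread",
    "envirotype_network",
    "summarize_network",
    "thermal_time_to_anthesis",
    "TT_SOW_EM_DEFAULT",
]

#: Default thermal time (°Cd) assumed from sowing to emergence when no
#: observed emergence date is available.
TT_SOW_EM_DEFAULT = 76.0


@dataclass
class Environment:
    """One field environment: location, calendar anchors and weather."""

    env_id: str
    latitude: float
    longitude: float
    sowing_date: dt.date
    weather: WeatherSeries
    emergence_date: dt.date | None = None

    def __post_init__(self):
        if not (-90 <= self.latitude <= 90):
            raise ConfigurationError(f"environment {self.env_id}: latitude out of range")
        if self.emergence_date is not None and self.emergence_date < self.sowing_date:
            raise ConfigurationError(
                f"environment {self.env_id}: emergence before sowing"
            )
        if not self.weather.covers(self.sowing_date):
            raise ConfigurationError(
                f"environment {self.env_id}: weather record does not cover sowing date"
            )


@dataclass
class EnvirotypeRecord:
    """Sensed daylength for one (environment, BVP reference) pair."""

    env_id: str
    reference: str
    bvp_cd: float
    sensitization_date: dt.date
    dls_h: float
    change_rate_h_per_day: float


def predict_emergence(
    env: Environment,
    cardinals: CardinalTemps = CardinalTemps(),
    tt_sow_em: float = TT_SOW_EM_DEFAULT,
) -> dt.date:
    """Emergence date: observed if recorded, else first day cumulative thermal
    time from sowing reaches ``tt_sow_em`` (default 76 °Cd)."""
    if env.emergence_date is not None:
        return env.emergence_date
    return date_at_threshold(env.weather, env.sowing_date, tt_sow_em, cardinals)


def _resolve_reference(ref) -> tuple[str, float]:
    """Accept a MaturityReference, GenotypeDev, label string or bare number."""
    if isinstance(ref, MaturityReference):
        return ref.label.value, ref.bvp_value
    if isinstance(ref, GenotypeDev):
        return ref.genotype_id, predict_bvp(ref)
    if isinstance(ref, str):
        if ref not in REFERENCE_BVP_CD:
            raise ConfigurationError(f"unknown maturity label {ref!r}")
        return ref, REFERENCE_BVP_CD[ref]
    return "custom", float(ref)


def sensed_daylength(
    env: Environment,
    reference,
    cardinals: CardinalTemps = CardinalTemps(),
    dl_params: DaylengthParams = DaylengthParams(),
    tt_sow_em: float = TT_SOW_EM_DEFAULT,
) -> EnvirotypeRecord:
    """Envirotype DLs for one environment and one BVP reference.

    ``reference`` may be a :class:`MaturityReference`, a
    :class:`GenotypeDev` (BVP predicted from its development parameters), a
    maturity label string, or a bare BVP value in °Cd.
    """
    label, bvp_cd = _resolve_reference(reference)
    if bvp_cd <= 0:
        raise ConfigurationError("BVP must be positive")
    emergence = predict_emergence(env, cardinals, tt_sow_em)
    sens_date = date_at_threshold(env.weather, emergence, bvp_cd, cardinals)
    doy = sens_date.timetuple().tm_yday
    dls = cbm_daylength(env.latitude, doy, dl_params)
    rate = photoperiod_change_rate(env.latitude, doy, dl_params)
    return EnvirotypeRecord(env.env_id, label, bvp_cd, sens_date, float(dls), float(rate))


def intra_env_spread(
    env: Environment,
    refs: dict | None = None,
    cardinals: CardinalTemps = CardinalTemps(),
    dl_params: DaylengthParams = DaylengthParams(),
    tt_sow_em: float = TT_SOW_EM_DEFAULT,
) -> dict:
    """DLs per maturity reference within one environment, plus pairwise
    differences (h) between maturity classes.

    Returns ``{"records": {label: EnvirotypeRecord}, "differences": {...}}``
    with differences late-early, late-median and median-early.
    """
    if refs is None:
        refs = dict(REFERENCE_BVP_CD)
    records = {
        label: sensed_daylength(env, bvp, cardinals, dl_params, tt_sow_em)
        for label, bvp in refs.items()
    }
    diffs = {}
    for hi, lo in (("late", "early"), ("late", "median"), ("median", "early")):
        if hi in records and lo in records:
            diffs[f"{hi}_minus_{lo}_h"] = records[hi].dls_h - records[lo].dls_h
    return {"records": records, "differences": diffs}


def envirotype_network(
    envs,
    refs: dict | None = None,
    cardinals: CardinalTemps = CardinalTemps(),
    dl_params: DaylengthParams = DaylengthParams(),
    tt_sow_em: float = TT_SOW_EM_DEFAULT,
) -> tuple[pd.DataFrame, list[dict]]:
    """Envirotype every environment in a network against every reference.

    Per-environment failures (e.g. insufficient weather) are collected and
    logged, not fatal.  Returns ``(table, failures)`` where the table has one
    row per (environment, reference) with columns env_id, reference,
    latitude, sensitization_date, dls_h, change_rate_h_per_day.
    """
    envs = list(envs)
    if not envs:
        raise ConfigurationError("envirotype_network needs at least one environment")
    if refs is None:
        refs = dict(REFERENCE_BVP_CD)
    rows, failures = [], []
    for env in envs:
        for label, bvp in refs.items():
            try:
                rec = sensed_daylength(env, bvp, cardinals, dl_params, tt_sow_em)
            except InsufficientWeatherError as exc:
                log.warning("envirotyping failed for %s/%s: %s", env.env_id, label, exc)
                failures.append({"env_id": env.env_id, "reference": label, "reason": str(exc)})
                continue
            rows.append(
                {
                    "env_id": rec.env_id,
                    "reference": str(label),
                    "latitude": env.latitude,
                    "longitude": env.longitude,
                    "bvp_cd": rec.bvp_cd,
                    "sensitization_date": rec.sensitization_date.isoformat(),
                    "dls_h": rec.dls_h,
                    "change_rate_h_per_day": rec.change_rate_h_per_day,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "env_id",
            "reference",
            "latitude",
            "longitude",
            "bvp_cd",
            "sensitization_date",
            "dls_h",
            "change_rate_h_per_day",
        ],
    )
    return table, failures


def summarize_network(table: pd.DataFrame, site_round: int = 2) -> dict:
    """Network-level DLs summary: range, mean, percentiles, and inter-annual
    differences between environments sharing a site (lat/lon rounded to
    ``site_round`` decimals)."""
    if table.empty:
        raise ConfigurationError("cannot summarize an empty envirotype table")
    dls = table["dls_h"].to_numpy()
    out = {
        "n_records": int(len(table)),
        "dls_min_h": float(dls.min()),
        "dls_max_h": float(dls.max()),
        "dls_range_h": float(dls.max() - dls.min()),
        "dls_mean_h": float(dls.mean()),
        "dls_p05_h": float(np.quantile(dls, 0.05)),
        "dls_p95_h": float(np.quantile(dls, 0.95)),
    }
    if {"latitude", "longitude"} <= set(table.columns):
        keyed = table.assign(
            site=table["latitude"].round(site_round).astype(str)
            + "_"
            + table["longitude"].round(site_round).astype(str)
        )
        diffs = []
        for (_, _), grp in keyed.groupby(["site", "reference"]):
            if len(grp) > 1:
                diffs.append(float(grp["dls_h"].max() - grp["dls_h"].min()))
        if diffs:
            out["same_site_max_dls_diff_h"] = float(np.max(diffs))
            out["same_site_mean_dls_diff_h"] = float(np.mean(diffs))
    return out


def thermal_time_to_anthesis(
    env: Environment,
    days_to_anthesis: float,
    cardinals: CardinalTemps = CardinalTemps(),
    tt_sow_em: float = TT_SOW_EM_DEFAULT,
) -> float:
    """Cumulative thermal time (°Cd) from emergence (observed or predicted)
    to anthesis, where anthesis = sowing date + ``days_to_anthesis`` days."""
    emergence = predict_emergence(env, cardinals, tt_sow_em)
    anthesis = env.sowing_date + dt.timedelta(days=int(round(days_to_anthesis)))
    if anthesis < emergence:
        raise ConfigurationError(
            f"environment {env.env_id}: anthesis {anthesis} precedes emergence {emergence}"
        )
    cum = accumulate(env.weather, emergence, cardinals)
    if pd.Timestamp(anthesis) not in cum.index:
        raise InsufficientWeatherError(
            f"weather record for environment {env.env_id} ends before anthesis {anthesis}",
            env_id=env.env_id,
        )
    return float(cum.loc[pd.Timestamp(anthesis)])
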