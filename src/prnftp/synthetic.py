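"""Synthetic weather, trial networks, genotype panels and forward-simulated
multi-environment trials (METs) with known ground truth.

The generator emulates the statistical structure the reaction-norm analysis
assumes, so every stage of the pipeline can be tested by parameter
recovery:

* daily temperature as an annual sinusoid (peak ~mid-July in the north,
  amplitude growing with latitude) plus Gaussian noise;
* a network of environments with latitudes spanning the maize-growing range
  of the Northern Hemisphere and planting dates staggered by latitude
  (spring sowing at temperate sites grading into autumn sowing in the
  tropics), which yields continuous coverage of sensed daylengths across
  the short-day/long-day range;
* a genotype panel with known flowering time per se (alpha), critical
  photoperiod (e), photoperiod sensitivity (beta), phyllochron and final
  leaf number (hence BVP), including a photoperiod-insensitive fraction
  (beta = 0) usable as latent-variable controls;
* phenotypes forward-simulated from the bilinear reaction norm read
  generatively:  Tt* = alpha + beta (DLs - e)+ + lambda_env + eps,
  with environment latent offsets lambda_env shared across genotypes and
  residual noise eps, then converted back to a calendar anthesis date by
  thermal-time threshold crossing.  The date discretization (<= one day's
  thermal-time increment) is the dominant round-trip error.

Truth tables carry every latent draw, so the simulator doubles as the exact
oracle for downstream stages.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bvp import BvpConstants, GenotypeDev, predict_bvp
from .daylength import DaylengthParams
from .envirotyping import (
    TT_SOW_EM_DEFAULT,
    Environment,
    predict_emergence,
    sensed_daylength,
)
from .exceptions import ConfigurationError
from .thermal_time import CardinalTemps, WeatherSeries, accumulate

log = logging.getLogger(__name__)

__all__ = ["GroupSpec", "SimConfig", "PRESETS", "simulate_weather", "simulate_network",
           "simulate_panel", "simulate_met", "get_preset"]

#: Simulation calendar base year (non-leap, so day-of-year arithmetic is exact).
BASE_YEAR = 2015


@dataclass(frozen=True)
class GroupSpec:
    """One ancestry/sensitivity group of a simulated genotype panel.

    Distributions are (mean, sd) of normals; ``beta`` is truncated at
    ``beta_floor`` (0 keeps insensitive genotypes exactly insensitive).
    """

    name: str
    fraction: float
    alpha_dist: tuple = (850.0, 40.0)
    e_dist: tuple = (13.0, 0.6)
    beta_dist: tuple = (60.0, 20.0)
    beta_floor: float = 5.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic MET generator.

    Temperatures follow tmean(d) = temp_mean_annual +
    temp_amplitude * sin(2π (DOY - 105) / 365) * (|lat| / 45) + N(0, temp_noise_sd),
    with tmin/tmax at ∓5 °C around the mean.  Sowing dates default to a
    latitude-staggered rule (see :func:`simulate_network`); supply
    ``sowing_doy_range`` for a uniform window instead.
    """

    seed: int = 0
    n_envs: int = 40
    latitude_range: tuple = (14.0, 50.0)
    sowing_doy_range: tuple | None = None
    network_style: str = "staggered"  # or "uniform", "bimodal"
    temp_mean_annual: float = 18.0
    temp_amplitude: float = 8.0
    temp_noise_sd: float = 1.5
    horizon_days: int = 250
    n_genotypes: int = 14
    prop_insensitive: float = 0.5
    groups: tuple | None = None
    p_tip_dist: tuple = (34.6, 3.0)
    lf_dist: tuple = (16.5, 1.5)
    latent_sd: float = 40.0
    resid_sd: float = 20.0
    cardinals: CardinalTemps = field(default_factory=CardinalTemps)
    dl_params: DaylengthParams = field(default_factory=DaylengthParams)
    tt_sow_em: float = TT_SOW_EM_DEFAULT

    def __post_init__(self):
        for name in ("temp_noise_sd", "latent_sd", "resid_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.latitude_range
        if not (lo <= hi):
            raise ConfigurationError("latitude_range must be ordered")
        if not (0.0 <= self.prop_insensitive <= 1.0):
            raise ConfigurationError("prop_insensitive must be in [0, 1]")

    def resolved_groups(self) -> tuple:
        if self.groups is not None:
            return tuple(self.groups)
        groups = []
        if self.prop_insensitive < 1.0:
            groups.append(GroupSpec("sensitive", 1.0 - self.prop_insensitive))
        if self.prop_insensitive > 0.0:
            groups.append(
                GroupSpec(
                    "insensitive",
                    self.prop_insensitive,
                    alpha_dist=(800.0, 40.0),
                    beta_dist=(0.0, 0.0),
                    beta_floor=0.0,
                )
            )
        return tuple(groups)


#: Named study templates.  "d4-like": a methodological-evaluation MET of 14
#: genotypes (half insensitive controls) in 37 environments with continuous
#: DLs coverage.  "d5-like": a diversity-panel MET of 236 genotypes in 19
#: environments whose DLs fall in two clusters (a few short-day tropical
#: sites, many long-day temperate sites) with a coverage gap between ~12.4
#: and ~14.5 h.
PRESETS: dict[str, SimConfig] = {
    "d4-like": SimConfig(n_envs=37, n_genotypes=14, prop_insensitive=0.5,
                         latent_sd=40.0, resid_sd=20.0),
    "d5-like": SimConfig(
        n_envs=19,
        n_genotypes=236,
        network_style="bimodal",
        groups=(
            GroupSpec("temperate", 109 / 236, alpha_dist=(800.0, 40.0),
                      beta_dist=(0.0, 0.0), beta_floor=0.0),
            GroupSpec("admixed", 61 / 236, alpha_dist=(850.0, 40.0),
                      beta_dist=(25.0, 15.0), beta_floor=0.0),
            GroupSpec("tropical", 66 / 236, alpha_dist=(900.0, 40.0),
                      beta_dist=(60.0, 25.0), beta_floor=0.0),
        ),
        latent_sd=40.0,
        resid_sd=20.0,
    ),
}


def get_preset(name: str, seed: int | None = None) -> SimConfig:
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, seed=seed) if seed is not None else cfg


def simulate_weather(
    latitude: float,
    year_start: dt.date,
    n_days: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    name: str | None = None,
) -> WeatherSeries:
    """Sinusoidal-plus-noise daily temperature series starting at ``year_start``."""
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    dates = pd.date_range(year_start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(float)
    tmean = (
        cfg.temp_mean_annual
        + cfg.temp_amplitude * np.sin(2 * np.pi * (doy - 105) / 365.0) * (abs(latitude) / 45.0)
        + rng.normal(0.0, cfg.temp_noise_sd, n_days)
    )
    frame = pd.DataFrame(
        {"tmin": tmean - 5.0, "tmax": tmean + 5.0, "tmean": tmean}, index=dates
    )
    return WeatherSeries(frame, name=name)


def _staggered_sowing_doy(lat: float, rng: np.random.Generator) -> int:
    """Spring sowing at temperate latitudes grading into autumn sowing in the
    tropics; produces continuous DLs coverage across the network."""
    doy = 270.0 - 4.6 * (lat - 14.0) + rng.uniform(-20.0, 20.0)
    return int(np.clip(round(doy), 1, 365))


def simulate_network(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[Environment]:
    """Simulate ``cfg.n_envs`` environments with attached weather."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.latitude_range
    envs = []
    if cfg.network_style == "bimodal":
        n_sd = max(3, round(0.16 * cfg.n_envs))
        specs = [(rng.uniform(14.0, 18.0), int(rng.uniform(280, 320))) for _ in range(n_sd)]
        specs += [
            (rng.uniform(35.0, 43.0), int(rng.uniform(110, 140)))
            for _ in range(cfg.n_envs - n_sd)
        ]
    else:
        lats = rng.uniform(lo, hi, cfg.n_envs)
        specs = []
        for lat in lats:
            if cfg.sowing_doy_range is not None and cfg.network_style == "uniform":
                doy = int(rng.integers(cfg.sowing_doy_range[0], cfg.sowing_doy_range[1] + 1))
            else:
                doy = _staggered_sowing_doy(lat, rng)
            specs.append((float(lat), doy))
    for i, (lat, sow_doy) in enumerate(specs):
        start = dt.date(BASE_YEAR, 1, 1)
        sowing = start + dt.timedelta(days=sow_doy - 1)
        n_days = sow_doy + cfg.horizon_days + 30
        wx = simulate_weather(lat, start, n_days, cfg, rng, name=f"E{i+1:03d}")
        envs.append(
            Environment(
                env_id=f"E{i+1:03d}",
                latitude=lat,
                longitude=float(rng.uniform(-100.0, 20.0)),
                sowing_date=sowing,
                weather=wx,
            )
        )
    return envs


def simulate_panel(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenotypeDev], pd.DataFrame]:
    """Simulate a genotype panel with known reaction-norm parameters.

    Returns (genotypes, truth) where truth has one row per genotype with
    columns genotype_id, group, alpha_cd, e_h, beta_cd_per_h, p_tip, lf,
    bvp_cd.  BVP is derived from phyllochron and final leaf number through
    the development formalism, so the same genotype drives both envirotyping
    and the forward phenotype model.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    groups = cfg.resolved_groups()
    counts = [int(round(g.fraction * cfg.n_genotypes)) for g in groups]
    counts[-1] = cfg.n_genotypes - sum(counts[:-1])
    genotypes, rows = [], []
    k = 0
    consts = BvpConstants()
    for g, cnt in zip(groups, counts):
        for _ in range(cnt):
            k += 1
            gid = f"G{k:03d}"
            p_tip = max(rng.normal(*cfg.p_tip_dist), 10.0)
            lf = max(rng.normal(*cfg.lf_dist), consts.l_pr_em + 2.0)
            alpha = rng.normal(*g.alpha_dist)
            beta = max(rng.normal(*g.beta_dist), g.beta_floor) if g.beta_dist[1] > 0 else g.beta_dist[0]
            e = rng.normal(*g.e_dist) if beta > 0 else np.nan
            dev = GenotypeDev(gid, phyllochron=p_tip, final_leaf_number=lf)
            genotypes.append(dev)
            rows.append(
                {
                    "genotype_id": gid,
                    "group": g.name,
                    "alpha_cd": float(alpha),
                    "e_h": float(e),
                    "beta_cd_per_h": float(beta),
                    "p_tip": float(p_tip),
                    "lf": float(lf),
                    "bvp_cd": float(predict_bvp(dev, consts)),
                }
            )
    return genotypes, pd.DataFrame(rows)


def simulate_met(
    envs: list[Environment],
    panel_truth: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate days to anthesis for every genotype x environment.

    For each pair: envirotype DLs from the genotype's true BVP, draw the
    target thermal time Tt* = alpha + beta (DLs - e)+ + lambda_env + eps,
    convert Tt* to the first calendar day its cumulative thermal time is
    reached, and report integer days from sowing.  Pairs whose Tt* is not
    reached within the weather record are dropped with a log entry
    (emulating real MET missingness).

    Returns (met, truth): ``met`` has genotype_id, env_id, days_to_anthesis;
    ``truth`` additionally carries dls_h, lambda_cd, eps_cd, tt_star_cd and
    the realized (date-discretized) tt_realized_cd.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    met_rows, truth_rows = [], []
    lambdas = {e.env_id: float(rng.normal(0.0, cfg.latent_sd)) if cfg.latent_sd > 0 else 0.0
               for e in envs}
    for env in envs:
        emergence = predict_emergence(env, cfg.cardinals, cfg.tt_sow_em)
        cum = accumulate(env.weather, emergence, cfg.cardinals)
        cum_vals = cum.to_numpy()
        lam = lambdas[env.env_id]
        for row in panel_truth.itertuples(index=False):
            rec = sensed_daylength(env, row.bvp_cd, cfg.cardinals, cfg.dl_params, cfg.tt_sow_em)
            photoperiod_term = (
                row.beta_cd_per_h * max(0.0, rec.dls_h - row.e_h)
                if row.beta_cd_per_h > 0
                else 0.0
            )
            eps = float(rng.normal(0.0, cfg.resid_sd)) if cfg.resid_sd > 0 else 0.0
            tt_star = row.alpha_cd + photoperiod_term + lam + eps
            idx = int(np.searchsorted(cum_vals, tt_star, side="left"))
            if idx >= len(cum_vals):
                log.warning(
                    "pair (%s, %s) dropped: target %.1f °Cd beyond weather record",
                    row.genotype_id, env.env_id, tt_star,
                )
                continue
            anthesis = cum.index[idx].date()
            met_rows.append(
                {
                    "genotype_id": row.genotype_id,
                    "env_id": env.env_id,
                    "days_to_anthesis": (anthesis - env.sowing_date).days,
                }
            )
            truth_rows.append(
                {
                    "genotype_id": row.genotype_id,
                    "env_id": env.env_id,
                    "emergence_date": emergence.isoformat(),
                    "sensitization_date": rec.sensitization_date.isoformat(),
                    "dls_h": rec.dls_h,
                    "lambda_cd": lam,
                    "eps_cd": eps,
                    "tt_star_cd": tt_star,
                    "tt_realized_cd": float(cum_vals[idx]),
                    "days_to_anthesis": (anthesis - env.sowing_date).days,
                }
            )
    met = pd.DataFrame(met_rows, columns=["genotype_id", "env_id", "days_to_anthesis"])
    truth = pd.DataFrame(truth_rows)
    return met, truth
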