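"""Reaction-norm estimation for flowering time plasticity.

The reaction norm relates thermal time from emergence to anthesis
(Tt_em-ant, °Cd) to the sensed daylength (DLs, h):

    Tt_em-ant = alpha + beta * (DLs - e)+          (bilinear "hinge" model)

where alpha is flowering time per se (°Cd), e the critical photoperiod (h),
beta the photoperiod sensitivity (°Cd h⁻¹) and (x)+ = max(0, x).  The hinge
is fitted by profile least squares: for a candidate threshold e the model is
linear in (alpha, beta), so OLS is solved on the hinge basis and the
residual sum of squares is minimized over e by a coarse scan over observed
values and midpoints followed by bounded continuous refinement inside the
best bracketing intervals.  Conditional OLS standard errors are reported for
alpha and beta; the threshold SE comes from a nonparametric bootstrap.

When DLs coverage is too sparse for threshold detection, the LD–SD method
fits a line through the short-day and long-day group means: each
observation's predictor is recoded to its group's mean DLs, shifted so the
SD mean is zero; the OLS intercept is then flowering time per se at the SD
mean and the slope an (attenuated or inflated, depending on where the true
threshold sits relative to the SD mean) estimate of photoperiod sensitivity.

Latent environmental effects (management, weather bias, drought, ...) are
removed before fitting by a control-genotype adjustment: photoperiod-
insensitive controls should flower at the same thermal time everywhere, so
each environment's deviation of its control mean from the across-environment
control mean is subtracted from every other genotype in that environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .exceptions import ConfigurationError, DegenerateFitError, FitError

__all__ = [
    "ControlGroup",
    "PRNFit",
    "latent_adjust",
    "fit_hinge",
    "classify_sd_ld",
    "fit_ld_sd",
    "fit_panel",
    "SD_LD_THRESHOLD_H",
]

#: Default DLs boundary (h) between short-day and long-day environments —
#: the average critical photoperiod estimated for tropical maize genotypes.
SD_LD_THRESHOLD_H = 13.5


@dataclass
class ControlGroup:
    """A set of photoperiod-insensitive control genotypes and the
    environments they adjust."""

    set_id: str
    genotype_ids: list
    env_ids: list


@dataclass
class PRNFit:
    """Estimated reaction-norm parameters for one genotype."""

    intercept: float
    slope: float
    rmse: float
    n_obs: int
    method: str
    threshold: float | None = None
    se_intercept: float | None = None
    se_threshold: float | None = None
    se_slope: float | None = None
    genotype_id: str | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.rmse < 0:
            raise ConfigurationError("rmse must be >= 0")


# ---------------------------------------------------------------------------
# latent-variable adjustment


def latent_adjust(met: pd.DataFrame, controls) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjust Tt_em-ant for latent environment effects via control genotypes.

    ``met`` needs columns ``genotype_id``, ``env_id``, ``tt_em_ant``.  Each
    environment must be mapped by exactly one control set and contain at
    least one observation of that set's genotypes.  For each set, the
    environment-specific mean control thermal time is compared with the
    across-environment mean m̄; the deviation is subtracted from all
    non-control genotypes in that environment, and control observations are
    set to m̄.

    Returns ``(adjusted, deviations)``; deviations has one row per
    environment with its set id and deviation in °Cd (summing to ~0 within
    each set).
    """
    controls = list(controls)
    required = {"genotype_id", "env_id", "tt_em_ant"}
    if not required <= set(met.columns):
        raise ConfigurationError(f"met table needs columns {sorted(required)}")
    env_to_set: dict[str, ControlGroup] = {}
    for cg in controls:
        for e in cg.env_ids:
            if e in env_to_set:
                raise ConfigurationError(
                    f"environment {e} mapped to more than one control set"
                )
            env_to_set[e] = cg
    unmapped = sorted(set(met["env_id"]) - set(env_to_set))
    if unmapped:
        raise ConfigurationError(f"environments without a control set: {unmapped}")

    adjusted = met.copy()
    dev_rows = []
    for cg in controls:
        sub = met[met["env_id"].isin(cg.env_ids) & met["genotype_id"].isin(cg.genotype_ids)]
        env_means = sub.groupby("env_id")["tt_em_ant"].mean()
        missing = sorted(set(cg.env_ids) & set(met["env_id"]) - set(env_means.index))
        if missing:
            raise ConfigurationError(
                f"control set {cg.set_id}: no control observations in environments {missing}"
            )
        m_bar = float(env_means.mean())
        dev = env_means - m_bar
        for env_id, d in dev.items():
            dev_rows.append({"env_id": env_id, "set_id": cg.set_id, "deviation_cd": float(d)})
        in_envs = adjusted["env_id"].isin(env_means.index)
        is_ctrl = adjusted["genotype_id"].isin(cg.genotype_ids)
        tgt = in_envs & ~is_ctrl
        adjusted.loc[tgt, "tt_em_ant"] = adjusted.loc[tgt, "tt_em_ant"] - adjusted.loc[
            tgt, "env_id"
        ].map(dev)
        adjusted.loc[in_envs & is_ctrl, "tt_em_ant"] = m_bar
    deviations = pd.DataFrame(dev_rows, columns=["env_id", "set_id", "deviation_cd"])
    return adjusted, deviations


# ---------------------------------------------------------------------------
# hinge (bilinear threshold) regression


def _hinge_ols(e: float, x: np.ndarray, y: np.ndarray):
    """Closed-form OLS of y on [1, (x-e)+]; returns (rss, alpha, beta)."""
    h = np.maximum(x - e, 0.0)
    hbar = h.mean()
    ybar = y.mean()
    hc = h - hbar
    yc = y - ybar
    shh = float(hc @ hc)
    syy = float(yc @ yc)
    if shh <= 0.0:
        return np.inf, np.nan, np.nan
    shy = float(hc @ yc)
    beta = shy / shh
    alpha = ybar - beta * hbar
    return max(syy - beta * shy, 0.0), alpha, beta


def _admissible(e: float, x: np.ndarray, min_side: int) -> bool:
    return (x < e).sum() >= min_side and (x > e).sum() >= min_side


def _profile_search(x: np.ndarray, y: np.ndarray, min_side: int):
    """Minimize hinge RSS over the threshold.

    Coarse scan over unique observed DLs values and midpoints, then bounded
    continuous refinement within the intervals bracketing the best coarse
    candidates (the profile RSS is smooth between consecutive data values,
    so its minimum may fall strictly inside an interval).  Returns
    (e, rss, alpha, beta) or None if no candidate is admissible.
    """
    xs = np.unique(x)
    coarse = np.concatenate([xs, (xs[:-1] + xs[1:]) / 2.0])
    cand = [e for e in coarse if _admissible(e, x, min_side)]
    if not cand:
        return None
    scored = sorted(cand, key=lambda e: _hinge_ols(e, x, y)[0])
    best_e = scored[0]
    best = (_hinge_ols(best_e, x, y), best_e)
    # refine inside intervals adjacent to the best few coarse candidates
    intervals = set()
    for e in scored[:3]:
        i = int(np.searchsorted(xs, e, side="right")) - 1
        for k in (i - 1, i, i + 1):
            if 0 <= k < len(xs) - 1:
                intervals.add((xs[k], xs[k + 1]))
    eps = 1e-9
    for a, b in intervals:
        mid = (a + b) / 2.0
        if not _admissible(mid, x, min_side):
            continue
        res = minimize_scalar(
            lambda e: _hinge_ols(e, x, y)[0],
            bounds=(a + eps, b - eps),
            method="bounded",
            options={"xatol": 1e-8},
        )
        fit = _hinge_ols(float(res.x), x, y)
        if fit[0] < best[0][0]:
            best = (fit, float(res.x))
    (rss, alpha, beta), e_hat = best
    return e_hat, rss, alpha, beta


def fit_hinge(
    points,
    min_side: int = 3,
    n_boot: int = 1000,
    seed: int | None = 0,
    allow_linear_limit: bool = True,
) -> PRNFit:
    """Fit the bilinear hinge reaction norm by profile least squares.

    ``points`` is an iterable of (dls_h, tt_em_ant) pairs or a 2-column
    array.  At least 8 points are required, with at least ``min_side``
    strictly below and above some candidate threshold.  The pure straight
    line (threshold at the minimum observed DLs, where the hinge degenerates
    to a line) is always evaluated as a fallback candidate; if it wins the
    fit is flagged ``linear_limit``.  A negative fitted slope is permitted
    but flagged ``negative_slope``.

    The threshold SE is a nonparametric bootstrap (``n_boot`` resamples,
    seeded); set ``n_boot=0`` to skip it.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigurationError("points must be (dls, tt) pairs")
    x, y = pts[:, 0], pts[:, 1]
    n = len(x)
    if n < 8:
        raise FitError(f"hinge fit needs >= 8 points, got {n}")
    if np.ptp(x) <= 0:
        raise FitError("DLs values have no spread; cannot fit a reaction norm")
    if np.ptp(y) <= 0:
        raise DegenerateFitError(
            "constant response: slope is 0 and the threshold is unidentifiable"
        )

    interior = _profile_search(x, y, min_side)
    e_lin = float(x.min())
    rss_lin, a_lin, b_lin = _hinge_ols(e_lin, x, y)
    flags = []
    if interior is None:
        raise FitError(
            "insufficient points on one side of every candidate threshold; "
            "cannot fit bilinear; use ld_sd"
        )
    e_hat, rss, alpha, beta = interior
    if allow_linear_limit and rss_lin < rss:
        e_hat, rss, alpha, beta = e_lin, rss_lin, a_lin, b_lin
        flags.append("linear_limit")
    if beta < 0:
        flags.append("negative_slope")

    rmse = float(np.sqrt(rss / n))
    # conditional OLS standard errors given the estimated threshold
    h = np.maximum(x - e_hat, 0.0)
    X = sm.add_constant(h)
    res = sm.OLS(y, X).fit()
    dof = max(n - 3, 1)  # three estimated parameters including the threshold
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_alpha = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
    se_beta = float(np.sqrt(sigma2 * xtx_inv[1, 1]))

    se_e = None
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            if np.ptp(xb) <= 0 or np.ptp(yb) <= 0:
                continue
            r = _profile_search(xb, yb, min_side)
            if r is not None:
                boots.append(r[0])
        if len(boots) > 1:
            se_e = float(np.std(boots, ddof=1))

    return PRNFit(
        intercept=float(alpha),
        slope=float(beta),
        rmse=rmse,
        n_obs=n,
        method="hinge",
        threshold=float(e_hat),
        se_intercept=se_alpha,
        se_threshold=se_e,
        se_slope=se_beta,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# LD–SD linear method


def classify_sd_ld(dls_h: float, threshold: float = SD_LD_THRESHOLD_H) -> str:
    """Classify a sensed daylength as short-day ("SD") or long-day ("LD").

    The boundary value itself is assigned to SD (closed lower segment).
    """
    if not (0.0 < dls_h < 24.0):
        raise ConfigurationError(f"dls {dls_h} outside (0, 24) h")
    return "LD" if dls_h > threshold else "SD"


def fit_ld_sd(points, threshold: float = SD_LD_THRESHOLD_H) -> PRNFit:
    """Fit the reaction norm by the LD–SD linear method.

    Observations are split into SD and LD groups at ``threshold``; each
    point's predictor is recoded to its group's mean DLs (computed over the
    genotype's own observed environments) and shifted so the SD mean is 0.
    OLS of Tt_em-ant on the recoded predictor then gives the intercept at
    the SD mean (flowering time per se) and the slope (photoperiod
    sensitivity).  With exactly two predictor levels this reduces to
    alpha = mean(tt | SD) and beta = (mean(tt|LD) - mean(tt|SD)) / (DLs gap)
    regardless of group sizes.  Requires >= 2 points per group.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigurationError("points must be (dls, tt) pairs")
    x, y = pts[:, 0], pts[:, 1]
    is_ld = x > threshold
    n_sd, n_ld = int((~is_ld).sum()), int(is_ld.sum())
    if n_sd < 2 or n_ld < 2:
        raise FitError(
            f"LD–SD fit needs >= 2 points per class (got SD={n_sd}, LD={n_ld}); "
            "all points in one class admit only an intercept-only summary"
        )
    sd_mean = float(x[~is_ld].mean())
    ld_mean = float(x[is_ld].mean())
    xr = np.where(is_ld, ld_mean - sd_mean, 0.0)
    X = sm.add_constant(xr)
    res = sm.OLS(y, X).fit()
    alpha, beta = float(res.params[0]), float(res.params[1])
    rss = float(res.ssr)
    return PRNFit(
        intercept=alpha,
        slope=beta,
        rmse=float(np.sqrt(rss / len(y))),
        n_obs=len(y),
        method="ld_sd",
        threshold=None,
        se_intercept=float(res.bse[0]),
        se_threshold=None,
        se_slope=float(res.bse[1]),
    )


# ---------------------------------------------------------------------------
# panel-level driver


def fit_panel(
    met: pd.DataFrame,
    method: str = "hinge",
    dls_col: str = "dls",
    tt_col: str = "tt_em_ant",
    sd_ld_threshold: float = SD_LD_THRESHOLD_H,
    min_side: int = 3,
    n_boot: int = 0,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit one reaction norm per genotype across a (possibly adjusted) MET.

    Returns ``(fits, failures)``: ``fits`` has one row per successfully
    fitted genotype (the (intercept, slope) columns are the trait space used
    to compare breeding pools); ``failures`` records genotypes whose
    coverage did not support the requested method, with the reason.
    """
    if method not in ("hinge", "ld_sd"):
        raise ConfigurationError(f"unknown method {method!r}")
    rows, failures = [], []
    for gid, grp in met.groupby("genotype_id", sort=True):
        pts = grp[[dls_col, tt_col]].to_numpy(float)
        try:
            if method == "hinge":
                fit = fit_hinge(pts, min_side=min_side, n_boot=n_boot, seed=seed)
            else:
                fit = fit_ld_sd(pts, threshold=sd_ld_threshold)
        except (FitError, ConfigurationError) as exc:
            failures.append({"genotype_id": gid, "reason": str(exc)})
            continue
        fit.genotype_id = gid
        rows.append(
            {
                "genotype_id": gid,
                "method": fit.method,
                "intercept": fit.intercept,
                "se_intercept": fit.se_intercept,
                "threshold": fit.threshold,
                "se_threshold": fit.se_threshold,
                "slope": fit.slope,
                "se_slope": fit.se_slope,
                "rmse": fit.rmse,
                "n_obs": fit.n_obs,
                "flags": ";".join(fit.flags),
            }
        )
    fits = pd.DataFrame(
        rows,
        columns=[
            "genotype_id",
            "method",
            "intercept",
            "se_intercept",
            "threshold",
            "se_threshold",
            "slope",
            "se_slope",
            "rmse",
            "n_obs",
            "flags",
        ],
    )
    return fits, pd.DataFrame(failures, columns=["genotype_id", "reason"])
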