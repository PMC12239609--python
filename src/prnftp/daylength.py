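"""Astronomical photoperiod: the CBM daylength model.

Daylength is computed from latitude and day of year with the closed-form
model of Forsythe et al. (the "CBM" model): a revolution angle θ of the
Earth around the Sun, the solar declination φ, and the day level as the
fraction of the day the Sun is above a horizon depressed by a twilight
coefficient p (degrees).  p = 6 corresponds to civil twilight, the
convention used for envirotyping photoperiod sensed by crops; p = 0 gives
sunrise-to-sunset daylength.

    θ = 0.2163108 + 2 atan(0.9671396 tan(0.00860 (J - 186)))
    φ = asin(0.39795 cos θ)
    D = 24 - (24/π) acos[(sin(p π/180) + sin(L π/180) sin φ)
                         / (cos(L π/180) cos φ)]

At polar latitudes the acos argument can leave [-1, 1]; it is clamped,
yielding 24 h (polar day) or 0 h (polar night), and a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["DaylengthParams", "cbm_daylength", "photoperiod_change_rate"]


@dataclass(frozen=True)
class DaylengthParams:
    """Twilight convention for daylength.

    ``twilight_coef`` is the solar depression angle (degrees) included in
    daylength; 6.0 = civil twilight (default), 0.0 = geometric sunrise/sunset.
    """

    twilight_coef: float = 6.0

    def __post_init__(self):
        if not (0.0 <= self.twilight_coef <= 18.0):
            raise ConfigurationError("twilight_coef must be in [0, 18] degrees")


def _revolution_angle(day_of_year):
    j = np.asarray(day_of_year, dtype=float)
    # day 366 folded onto 365: sub-minute effect, keeps the formula 365-periodic
    j = np.where(j > 365, 365.0, j)
    return 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (j - 186.0)))


def cbm_daylength(latitude, day_of_year, params: DaylengthParams = DaylengthParams()):
    """Daylength in hours at ``latitude`` (°N, in [-90, 90]) on ``day_of_year``.

    Vectorized over both arguments.  Polar day/night is clamped to 24 h / 0 h
    with a warning.
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ConfigurationError("latitude must be within [-90, 90] degrees")
    theta = _revolution_angle(day_of_year)
    phi = np.arcsin(0.39795 * np.cos(theta))
    p_rad = np.deg2rad(params.twilight_coef)
    lat_rad = np.deg2rad(lat)
    arg = (np.sin(p_rad) + np.sin(lat_rad) * np.sin(phi)) / (np.cos(lat_rad) * np.cos(phi))
    clipped = np.clip(arg, -1.0, 1.0)
    if np.any(np.abs(arg) > 1.0):
        warnings.warn(
            "polar day/night encountered; daylength clamped to 0 or 24 h",
            RuntimeWarning,
            stacklevel=2,
        )
    d = 24.0 - (24.0 / np.pi) * np.arccos(clipped)
    return d if d.ndim else float(d)


def photoperiod_change_rate(latitude, day_of_year, params: DaylengthParams = DaylengthParams()):
    """Daily rate of photoperiodic change (h day⁻¹) by central difference.

    (D(J+1) - D(J-1)) / 2 on a 365-day cycle; the year boundary wraps so the
    rate is defined for every day.  Positive in the lengthening half of the
    year, negative in the shortening half, ~0 at the solstices.
    """
    j = np.asarray(day_of_year, dtype=float)
    j = np.where(j > 365, 365.0, j)
    j_prev = np.where(j - 1 < 1, 365.0 + (j - 1), j - 1)
    j_next = np.where(j + 1 > 365, (j + 1) - 365.0, j + 1)
    rate = (cbm_daylength(latitude, j_next, params) - cbm_daylength(latitude, j_prev, params)) / 2.0
    return rate if np.ndim(rate) else float(rate)
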