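"""Basic vegetative phase (BVP) prediction.

The BVP is the thermal time from crop emergence to tassel initiation under
short days — a proxy for the duration until a maize genotype becomes
sensitized to photoperiod.  Tassel initiation occurs when the last leaf
primordium is formed, and primordium formation and leaf-tip appearance
proceed at proportional rates, so the BVP can be predicted from two easily
measured development parameters:

    Tt_em-TI = (P_tip / alpha_phyll_plast) * (LF - L_pr_em)

where P_tip is the phyllochron (°Cd per leaf tip), LF the final leaf
number, alpha_phyll_plast the phyllochron/plastochron ratio (literature
range 1.58–1.85, default 1.73) and L_pr_em the number of primordia already
formed at emergence (default 5.5).

Reference maturity classes (early / median / late) are fixed percentile
values of a large-panel BVP distribution (239 / 326 / 434 °Cd) used as
common references when genotype-specific development data are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "GenotypeDev",
    "BvpConstants",
    "MaturityReference",
    "MaturityLabel",
    "predict_bvp",
    "reference_bvp",
    "bvp_percentiles",
]

#: Reference BVP values (°Cd) at the 5th / 50th / 95th percentiles of a
#: 284-genotype panel, labelling early, median and late maturity classes.
REFERENCE_BVP_CD = {"early": 239.0, "median": 326.0, "late": 434.0}


@dataclass(frozen=True)
class BvpConstants:
    """Constants of the BVP predictor.

    ``alpha_phyll_plast``: phyllochron/plastochron ratio (dimensionless).
    ``l_pr_em``: leaf primordia present at crop emergence (4–5 in the embryo
    plus ~2 formed before emergence).
    """

    alpha_phyll_plast: float = 1.73
    l_pr_em: float = 5.5

    def __post_init__(self):
        if self.alpha_phyll_plast <= 0:
            raise ConfigurationError("alpha_phyll_plast must be positive")
        if self.l_pr_em <= 0:
            raise ConfigurationError("l_pr_em must be positive")


@dataclass
class GenotypeDev:
    """Genotype-level development parameters.

    ``bvp`` may be supplied directly (measured values override prediction);
    otherwise it is derived from phyllochron and final leaf number.  Leaf
    numbers may be fractional (they are typically BLUEs).
    """

    genotype_id: str
    phyllochron: float | None = None
    final_leaf_number: float | None = None
    bvp: float | None = None

    def __post_init__(self):
        if self.bvp is None and (self.phyllochron is None or self.final_leaf_number is None):
            raise ConfigurationError(
                f"genotype {self.genotype_id}: need either bvp or "
                "(phyllochron, final_leaf_number)"
            )
        if self.phyllochron is not None and self.phyllochron <= 0:
            raise ConfigurationError(f"genotype {self.genotype_id}: phyllochron must be > 0")
        if self.bvp is not None and self.bvp <= 0:
            raise ConfigurationError(f"genotype {self.genotype_id}: bvp must be > 0")


class MaturityLabel(str, Enum):
    early = "early"
    median = "median"
    late = "late"
    custom = "custom"


@dataclass(frozen=True)
class MaturityReference:
    """A named BVP reference value (°Cd) for envirotyping."""

    label: MaturityLabel
    bvp_value: float

    def __post_init__(self):
        if self.bvp_value <= 0:
            raise ConfigurationError("reference BVP must be positive")


def predict_bvp(g: GenotypeDev, constants: BvpConstants = BvpConstants()) -> float:
    """Predicted BVP (°Cd): (P_tip / alpha) * (LF - L_pr_em).

    If ``g.bvp`` is supplied it is returned unchanged.  Raises if the final
    leaf number does not exceed the primordia count at emergence (the phase
    would have non-positive duration).
    """
    if g.bvp is not None:
        return float(g.bvp)
    if g.final_leaf_number <= constants.l_pr_em:
        raise ConfigurationError(
            f"genotype {g.genotype_id}: final leaf number {g.final_leaf_number} "
            f"must exceed primordia at emergence ({constants.l_pr_em})"
        )
    return (g.phyllochron / constants.alpha_phyll_plast) * (
        g.final_leaf_number - constants.l_pr_em
    )


def reference_bvp(label) -> MaturityReference:
    """Reference maturity class -> BVP value (°Cd): early 239, median 326, late 434."""
    key = label.value if isinstance(label, MaturityLabel) else str(label)
    if key not in REFERENCE_BVP_CD:
        raise ConfigurationError(
            f"unknown maturity label {label!r}; expected one of {sorted(REFERENCE_BVP_CD)}"
        )
    return MaturityReference(MaturityLabel(key), REFERENCE_BVP_CD[key])


def bvp_percentiles(bvps, probs):
    """Empirical quantiles of a BVP sample (linear interpolation between
    order statistics).  ``probs`` in [0, 1]."""
    v = np.asarray(list(bvps), dtype=float)
    p = np.asarray(list(probs), dtype=float)
    if v.size < 2:
        raise ConfigurationError("need at least 2 BVP values for percentiles")
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("probs must lie in [0, 1]")
    return np.quantile(v, p, method="linear")
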