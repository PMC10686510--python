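"""Chemical flame-retardant (CFR) exposure-potential model.

Exposure potential while furniture is in use is scored from five
dimensions: likelihood of use by a young child (low relative body
weight), bare-skin contact (dermal migration), mouthing (oral
migration), cumulative use (duration of contact) and surface area (size
of the CFR reservoir).  The four behavioural dimensions are 1-5 Likert
judgements; surface area is measured in m^2 and log-transformed onto the
same scale so that small changes in small items matter as much as large
changes in large ones.  With no rationale for weighting any dimension
more heavily, the overall score is the arithmetic mean of the five, so
it is a *relative* potential for exposure between product types, not a
dose estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .catalogue import ExposureEvaluation
from .config import ThresholdConfig
from .errors import ValidationError

__all__ = ["surface_area_score", "ExposureDimensionScores", "dimension_scores", "exposure_score"]


def surface_area_score(area: float, sa_min: float = 0.05, sa_max: float = 10.0,
                       integer_binning: bool = True) -> float:
    """Log-transform a surface area (m^2) onto the 1-5 scale.

    Linear in ln(area) between the anchors ``sa_min`` -> 1 and
    ``sa_max`` -> 5, clamped outside.  With ``integer_binning`` the
    result is rounded half-up to a whole Likert point, which keeps
    five-dimension mean scores on a 0.2 grid.
    """
    if area <= 0:
        raise ValidationError(f"surface area must be positive, got {area}")
    if sa_min >= sa_max:
        raise ValueError("sa_min must be strictly less than sa_max")
    raw = 1.0 + 4.0 * (math.log(area) - math.log(sa_min)) / (math.log(sa_max) - math.log(sa_min))
    clamped = min(5.0, max(1.0, raw))
    if integer_binning:
        return float(math.floor(clamped + 0.5))
    return clamped


@dataclass(frozen=True)
class ExposureDimensionScores:
    child_use: float
    bare_skin: float
    mouthing: float
    cumulative_use: float
    surface_area_score: float


def dimension_scores(evaluation: ExposureEvaluation, config: ThresholdConfig | None = None) -> ExposureDimensionScores:
    cfg = config or ThresholdConfig()
    return ExposureDimensionScores(
        child_use=float(evaluation.child_use),
        bare_skin=float(evaluation.bare_skin),
        mouthing=float(evaluation.mouthing),
        cumulative_use=float(evaluation.cumulative_use),
        surface_area_score=surface_area_score(
            evaluation.surface_area, cfg.sa_min, cfg.sa_max, cfg.sa_integer_binning
        ),
    )


def exposure_score(evaluation: ExposureEvaluation, config: ThresholdConfig | None = None) -> float:
    """Overall CFR exposure potential: equal-weight mean of the five dimensions."""
    ds = dimension_scores(evaluation, config)
    return (ds.child_use + ds.bare_skin + ds.mouthing + ds.cumulative_use + ds.surface_area_score) / 5.0
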