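"""Configuration objects for the furniture fire-safety matrix.

All tunable constants of the scoring pipeline live in
:class:`ThresholdConfig` so that every stage (transforms, aggregation,
clustering, sensitivity) reads from one validated source of truth.
:class:`PipelineConfig` adds run-level concerns (paths, seed, figures).
"""

from __future__ import annotations

from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Likert scale bounds shared by every ordinal questionnaire field.
LIKERT_MIN = 1
LIKERT_MAX = 5


class QuartileMethod(str, Enum):
    """Percentile estimator used by the lowest-quartile aggregation.

    Values name the estimators of ``numpy.percentile``;  ``linear`` is the
    classic type-7 linear interpolation between order statistics.
    """

    linear = "linear"
    lower = "lower"
    higher = "higher"
    nearest = "nearest"
    midpoint = "midpoint"
    median_unbiased = "median_unbiased"


class LinkageMethod(str, Enum):
    single = "single"
    complete = "complete"
    average = "average"
    ward = "ward"


class QuadrantRule(str, Enum):
    """How the x/y thresholds of the quadrant plot are derived."""

    midrange = "midrange"
    median = "median"
    explicit = "explicit"


class ConsensusRule(str, Enum):
    """Arithmetic stand-in for the moderated consolidation session."""

    median_round_half_up = "median-round-half-up"
    mean = "mean"


class IgnitionRule(str, Enum):
    """How the junction score combines with ornateness when gated out.

    ``mean_exclude``: dimension = mean(junction, ornateness) when the
    narrative gate is active, ornateness alone otherwise (default).
    ``mean_zero``: a gated-out junction contributes a literal 0 to the
    two-value mean.
    ``pooled``: junction and ornateness enter the quartile pool as separate
    values (junction dropped when gated out).
    """

    mean_exclude = "mean-exclude"
    mean_zero = "mean-zero"
    pooled = "pooled"


DEFAULT_IGNITION_LEXICON = (
    "cigarette",
    "smoker",
    "smoking",
    "candle",
    "lighter",
    "match",
    "pipe",
)


class ThresholdConfig(BaseModel):
    """Scoring-model constants.

    Parameters
    ----------
    volume_cap
        Combustible volume (m^3) at which the spread score saturates at 5.
        Default 0.009 m^3, the volume of a small cushion above which
        post-ignition flame spread is assumed guaranteed.
    junction_cap
        Junction count at which the junction score saturates (an open box).
    sa_min, sa_max
        Surface-area anchors (m^2) of the log transform mapping to 1 and 5.
    sa_integer_binning
        Round the surface-area score half-up to an integer, so that
        exposure scores averaged over five integer dimensions fall on a
        0.2 grid.
    ignition_lexicon
        Lower-cased keyword stems; a narrative mentioning any of them
        (word-initial match) activates the junction gate.
    cut_height
        Dendrogram cut height separating clusters from outliers.
    sensitivity_cap
        Ceiling applied to contact scores under systematic-error imputation.
    jitter_amplitude
        Half-width of the uniform jitter added to sensitivity-plot
        coordinates (never to scores).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    volume_cap: float = Field(default=0.009, gt=0)
    junction_cap: int = Field(default=4, ge=1)
    likert_min: int = LIKERT_MIN
    likert_max: int = LIKERT_MAX
    sa_min: float = Field(default=0.05, gt=0)
    sa_max: float = Field(default=10.0, gt=0)
    sa_integer_binning: bool = True
    quartile_method: QuartileMethod = QuartileMethod.linear
    linkage_method: LinkageMethod = LinkageMethod.average
    cut_height: float = Field(default=0.56, ge=0)
    sensitivity_cap: int = 5
    ignition_lexicon: tuple[str, ...] = DEFAULT_IGNITION_LEXICON
    ignition_rule: IgnitionRule = IgnitionRule.mean_exclude
    quadrant_threshold_rule: QuadrantRule = QuadrantRule.midrange
    jitter_amplitude: float = Field(default=0.05, ge=0)
    consensus_rule: ConsensusRule = ConsensusRule.median_round_half_up

    @model_validator(mode="after")
    def _check_anchors(self) -> "ThresholdConfig":
        if self.sa_min >= self.sa_max:
            raise ValueError("sa_min must be strictly less than sa_max")
        if not self.ignition_lexicon:
            raise ValueError("ignition_lexicon must be non-empty")
        if self.likert_min >= self.likert_max:
            raise ValueError("likert_min must be below likert_max")
        return self


class PipelineConfig(BaseModel):
    """Run-level configuration: thresholds plus paths, seed and toggles."""

    model_config = ConfigDict(extra="forbid")

    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    fire_input: Optional[Path] = None
    exposure_input: Optional[Path] = None
    output_dir: Path = Path("fsmatrix_out")
    seed: int = 0
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)
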