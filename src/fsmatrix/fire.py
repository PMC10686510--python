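"""Fire-risk scoring model.

Fire injury is treated as a failure chain: a user must come into contact
with an ignition source, the item must ignite, the fire must spread, and
the user must be unable to react.  Each link is a model dimension scored
on (or transformed to) a 1-5 scale:

* **contact** — likelihood of contact with an ignition source (Likert);
* **ignition** — composite of the junction-count transform and surface
  ornateness; the junction contribution only counts when the evaluators'
  ignition narrative mentions candles or smokers' materials, because
  junctions are only dangerous to ignition sources that can fall into
  them;
* **spread** — combustible volume through a capped linear transform;
* **reactivity** — reactive capacity of the likely user (Likert).

The aggregate risk is the *lowest quartile* of the dimension scores:
weighted toward the weakest links of the chain without letting the single
lowest score dictate the output.  Injury risk uses all four dimensions;
property-damage risk omits reactivity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalogue import FireEvaluation
from .config import IgnitionRule, QuartileMethod, ThresholdConfig
from .errors import ValidationError

__all__ = [
    "junction_score",
    "ignition_gate",
    "volume_score",
    "ignition_dimension_score",
    "lower_quartile",
    "FireDimensionScores",
    "dimension_scores",
    "injury_risk_score",
    "damage_risk_score",
]


def junction_score(junction_count: int, cap: int = 4) -> int:
    """Map a junction count to a 1-5 score: 0->1, 1->2, 2->3, 3->4, >=cap->5.

    An item with four junctions is effectively an open box — a dropped
    smouldering object can only roll into a junction — so the score
    saturates there.
    """
    if junction_count != int(junction_count) or junction_count < 0:
        raise ValidationError(f"junction_count must be a non-negative integer, got {junction_count}")
    return min(int(junction_count), cap) + 1


def ignition_gate(narrative: str, lexicon: Sequence[str]) -> bool:
    """True iff the ignition narrative mentions any lexicon stem.

    Matching is case-insensitive and word-initial, so the stem ``smok``
    hits both "smokers" and "smoking" but "besmoked" does not.
    """
    if not lexicon:
        raise ValueError("ignition lexicon must be non-empty")
    text = narrative.lower()
    return any(re.search(r"\b" + re.escape(stem.lower()), text) for stem in lexicon)


def volume_score(volume: float, cap: float = 0.009) -> float:
    """Capped linear transform of combustible volume (m^3) to a 1-5 score.

    Risk rises linearly from 1 at zero volume to 5 at ``cap`` and
    saturates beyond; the default cap of 0.009 m^3 (a small cushion) is
    the volume above which flame spread is assumed guaranteed.
    """
    if volume < 0:
        raise ValidationError(f"combustible volume must be non-negative, got {volume}")
    if cap <= 0:
        raise ValueError("volume cap must be positive")
    return 1.0 + 4.0 * min(volume, cap) / cap


def ignition_dimension_score(jscore: float, gate: bool, ornateness: float,
                             rule: IgnitionRule = IgnitionRule.mean_exclude) -> float:
    """Combine junction and ornateness scores into the ignition dimension.

    With the gate active the default is the arithmetic mean of the two;
    gated out, the junction contribution is removed and ornateness stands
    alone.  ``mean_zero`` instead averages a literal 0 junction score.
    (Under ``pooled`` the two scores enter the quartile pool separately;
    the combination happens in the aggregate, not here.)
    """
    if gate:
        return (jscore + ornateness) / 2
    if rule == IgnitionRule.mean_zero:
        return (0.0 + ornateness) / 2
    return float(ornateness)


def lower_quartile(values: Sequence[float], method: QuartileMethod = QuartileMethod.linear) -> float:
    """25th percentile of the dimension scores under the configured estimator.

    The default is linear interpolation between order statistics (the
    common spreadsheet/statistical default): at sorted index
    ``0.25 * (n - 1)``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("lower_quartile of an empty sequence is undefined")
    return float(np.percentile(arr, 25, method=QuartileMethod(method).value))


@dataclass(frozen=True)
class FireDimensionScores:
    """Per-dimension 1-5 scores for one evaluated item."""

    contact_score: float
    ignition_score: float
    spread_score: float
    reactivity_score: float
    junction_gate_active: bool
    junction_score: float  # transformed junction count, pre-combination
    ornateness_score: float


def dimension_scores(evaluation: FireEvaluation, config: ThresholdConfig | None = None) -> FireDimensionScores:
    """Apply the transforms to a consolidated evaluation."""
    cfg = config or ThresholdConfig()
    gate = ignition_gate(evaluation.ignition_narrative, cfg.ignition_lexicon)
    jscore = junction_score(evaluation.junction_count, cfg.junction_cap)
    return FireDimensionScores(
        contact_score=float(evaluation.contact),
        ignition_score=ignition_dimension_score(jscore, gate, evaluation.ornateness, cfg.ignition_rule),
        spread_score=volume_score(evaluation.combustible_volume, cfg.volume_cap),
        reactivity_score=float(evaluation.reactive_capacity),
        junction_gate_active=gate,
        junction_score=float(jscore),
        ornateness_score=float(evaluation.ornateness),
    )


def _pool(ds: FireDimensionScores, cfg: ThresholdConfig, *, with_reactivity: bool) -> list[float]:
    if cfg.ignition_rule == IgnitionRule.pooled:
        # junction enters the quartile pool as its own value, gated in only
        pool = [ds.contact_score]
        if ds.junction_gate_active:
            pool.append(ds.junction_score)
        pool.extend([ds.ornateness_score, ds.spread_score])
    else:
        pool = [ds.contact_score, ds.ignition_score, ds.spread_score]
    if with_reactivity:
        pool.append(ds.reactivity_score)
    return pool


def injury_risk_score(evaluation: FireEvaluation, config: ThresholdConfig | None = None) -> float:
    """Overall injury-risk score: lowest quartile over all four dimensions."""
    cfg = config or ThresholdConfig()
    ds = dimension_scores(evaluation, cfg)
    return lower_quartile(_pool(ds, cfg, with_reactivity=True), cfg.quartile_method)


def damage_risk_score(evaluation: FireEvaluation, config: ThresholdConfig | None = None) -> float:
    """Property-damage risk: as injury but without the reactivity dimension."""
    cfg = config or ThresholdConfig()
    ds = dimension_scores(evaluation, cfg)
    return lower_quartile(_pool(ds, cfg, with_reactivity=False), cfg.quartile_method)
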