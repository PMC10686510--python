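"""Furniture catalogue data model, questionnaire CSV I/O and packaged fixtures.

The pipeline scores *furniture product types*, each represented by a
relatively low-risk and a relatively high-risk example item.  Evaluators
fill one questionnaire per item: a *fire* questionnaire (contact with an
ignition source, junction count, ornateness, reactive capacity,
combustible volume, plus a free-text ignition narrative) and an
*exposure* questionnaire (child use, bare-skin contact, mouthing,
cumulative use, surface area).  This module defines those records,
validated CSV readers/writers for them, the consolidation rule that
stands in for the evaluators' consensus session, and loaders for the
reference tables shipped with the package.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

from .config import LIKERT_MAX, LIKERT_MIN, ConsensusRule
from .errors import (
    DuplicateRecordError,
    FixtureIntegrityError,
    SchemaError,
    ValidationError,
)

CONSENSUS_ID = "consensus"

FIRE_HEADER = [
    "type_id",
    "variant",
    "evaluator",
    "contact",
    "junction_count",
    "ornateness",
    "reactive_capacity",
    "combustible_volume_m3",
    "ignition_narrative",
]
EXPOSURE_HEADER = [
    "type_id",
    "variant",
    "evaluator",
    "child_use",
    "bare_skin",
    "mouthing",
    "cumulative_use",
    "surface_area_m2",
]
SCORES_HEADER = ["type_id", "variant", "injury_risk", "damage_risk", "exposure_score"]

Variant = Literal["low", "high"]


@dataclass(frozen=True)
class FurnitureType:
    """One furniture product type in the catalogue."""

    type_id: str
    display_name: str
    small_child_product: bool = False
    notes: str = ""

    def __post_init__(self):
        if not self.type_id:
            raise ValidationError("type_id must be non-empty")


@dataclass(frozen=True)
class ItemVariant:
    """The relatively low- or high-risk example item of a type."""

    type_id: str
    variant: Variant
    description: str = ""

    def __post_init__(self):
        if self.variant not in ("low", "high"):
            raise ValidationError(f"variant must be 'low' or 'high', got {self.variant!r}")


def _check_ordinal(name: str, value: float, evaluator_id: str) -> None:
    if not (LIKERT_MIN <= value <= LIKERT_MAX):
        raise ValidationError(f"{name}={value} outside [{LIKERT_MIN},{LIKERT_MAX}]")
    # raw evaluator scores are whole Likert points; consensus records may
    # carry fractional values (e.g. a mean rule)
    if evaluator_id != CONSENSUS_ID and value != int(value):
        raise ValidationError(f"{name}={value} must be an integer for raw records")


@dataclass(frozen=True)
class FireEvaluation:
    """One evaluator's fire questionnaire for one item variant."""

    item: ItemVariant
    evaluator_id: str
    contact: float
    junction_count: float
    ornateness: float
    reactive_capacity: float
    combustible_volume: float
    ignition_narrative: str = ""

    flavour = "fire"

    def __post_init__(self):
        for name in ("contact", "ornateness", "reactive_capacity"):
            _check_ordinal(name, getattr(self, name), self.evaluator_id)
        if self.junction_count < 0:
            raise ValidationError(f"junction_count={self.junction_count} is negative")
        if self.evaluator_id != CONSENSUS_ID and self.junction_count != int(self.junction_count):
            raise ValidationError("junction_count must be an integer for raw records")
        if self.combustible_volume < 0:
            raise ValidationError(f"combustible_volume={self.combustible_volume} is negative")


@dataclass(frozen=True)
class ExposureEvaluation:
    """One evaluator's exposure questionnaire for one item variant."""

    item: ItemVariant
    evaluator_id: str
    child_use: float
    bare_skin: float
    mouthing: float
    cumulative_use: float
    surface_area: float

    flavour = "exposure"

    def __post_init__(self):
        for name in ("child_use", "bare_skin", "mouthing", "cumulative_use"):
            _check_ordinal(name, getattr(self, name), self.evaluator_id)
        if self.surface_area <= 0:
            raise ValidationError(f"surface_area={self.surface_area} must be positive")


EvaluationRecord = Union[FireEvaluation, ExposureEvaluation]


@dataclass(frozen=True)
class ItemScores:
    """Scored item variant as written to scores.csv."""

    type_id: str
    variant: Variant
    injury_risk: float
    damage_risk: float
    exposure_score: float


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _parse_number(text: str, name: str, row: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"field {name}={text!r} is not numeric", row=row) from None


def read_evaluations(path: Path | str, flavour: Literal["fire", "exposure"]) -> list[EvaluationRecord]:
    """Read and validate a questionnaire CSV.

    Row order is preserved.  Raises :class:`SchemaError` for a missing or
    misnamed column, :class:`ValidationError` (with the offending row
    index) for out-of-range values, and :class:`DuplicateRecordError`
    when two rows share an (item, evaluator) key.
    """
    if flavour not in ("fire", "exposure"):
        raise ValueError(f"unknown flavour {flavour!r}")
    header = FIRE_HEADER if flavour == "fire" else EXPOSURE_HEADER
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            got = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header {header}") from None
        if got != header:
            missing = [c for c in header if c not in got]
            if missing:
                raise SchemaError(f"{path}: missing column(s) {missing}")
            raise SchemaError(f"{path}: header {got} does not match {header}")
        records: list[EvaluationRecord] = []
        seen: set[tuple[str, str, str]] = set()
        for i, row in enumerate(reader):
            if len(row) != len(header):
                raise ValidationError(f"expected {len(header)} fields, got {len(row)}", row=i)
            rec = dict(zip(header, row))
            item = ItemVariant(type_id=rec["type_id"], variant=rec["variant"])  # type: ignore[arg-type]
            key = (rec["type_id"], rec["variant"], rec["evaluator"])
            if key in seen:
                raise DuplicateRecordError(f"duplicate record for {key} at row {i}")
            seen.add(key)
            try:
                if flavour == "fire":
                    records.append(
                        FireEvaluation(
                            item=item,
                            evaluator_id=rec["evaluator"],
                            contact=_parse_number(rec["contact"], "contact", i),
                            junction_count=_parse_number(rec["junction_count"], "junction_count", i),
                            ornateness=_parse_number(rec["ornateness"], "ornateness", i),
                            reactive_capacity=_parse_number(rec["reactive_capacity"], "reactive_capacity", i),
                            combustible_volume=_parse_number(rec["combustible_volume_m3"], "combustible_volume_m3", i),
                            ignition_narrative=rec["ignition_narrative"],
                        )
                    )
                else:
                    records.append(
                        ExposureEvaluation(
                            item=item,
                            evaluator_id=rec["evaluator"],
                            child_use=_parse_number(rec["child_use"], "child_use", i),
                            bare_skin=_parse_number(rec["bare_skin"], "bare_skin", i),
                            mouthing=_parse_number(rec["mouthing"], "mouthing", i),
                            cumulative_use=_parse_number(rec["cumulative_use"], "cumulative_use", i),
                            surface_area=_parse_number(rec["surface_area_m2"], "surface_area_m2", i),
                        )
                    )
            except ValidationError as exc:
                if exc.row is None:
                    raise ValidationError(str(exc), row=i) from None
                raise
    return records


def write_evaluations(records: Sequence[EvaluationRecord], path: Path | str) -> None:
    """Write questionnaire records in the canonical CSV layout."""
    if not records:
        raise ValueError("no records to write")
    flavour = records[0].flavour
    header = FIRE_HEADER if flavour == "fire" else EXPOSURE_HEADER
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for r in records:
            if r.flavour != flavour:
                raise ValueError("mixed fire/exposure records in one file")
            if flavour == "fire":
                w.writerow(
                    [
                        r.item.type_id,
                        r.item.variant,
                        r.evaluator_id,
                        _fmt(r.contact),
                        _fmt(r.junction_count),
                        _fmt(r.ornateness),
                        _fmt(r.reactive_capacity),
                        repr(r.combustible_volume),
                        r.ignition_narrative,
                    ]
                )
            else:
                w.writerow(
                    [
                        r.item.type_id,
                        r.item.variant,
                        r.evaluator_id,
                        _fmt(r.child_use),
                        _fmt(r.bare_skin),
                        _fmt(r.mouthing),
                        _fmt(r.cumulative_use),
                        repr(r.surface_area),
                    ]
                )


def _fmt(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


def write_scores(records: Sequence[ItemScores], path: Path | str) -> None:
    """Write scored items to CSV with 6-decimal fixed formatting.

    Refuses empty input and creates no file in that case.
    """
    if not records:
        raise ValueError("no scored items to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SCORES_HEADER)
        for r in records:
            w.writerow(
                [
                    r.type_id,
                    r.variant,
                    f"{r.injury_risk:.6f}",
                    f"{r.damage_risk:.6f}",
                    f"{r.exposure_score:.6f}",
                ]
            )


def read_scores(path: Path | str) -> list[ItemScores]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        got = next(reader)
        if got != SCORES_HEADER:
            raise SchemaError(f"{path}: header {got} does not match {SCORES_HEADER}")
        return [
            ItemScores(row[0], row[1], float(row[2]), float(row[3]), float(row[4]))  # type: ignore[arg-type]
            for row in reader
        ]


# ---------------------------------------------------------------------------
# Consolidation
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _median_half_up(values: Sequence[float]) -> float:
    med = float(np.median(values))
    frac = med - math.floor(med)
    if math.isclose(frac, 0.5):
        return math.floor(med) + 1.0
    return med


def consolidate_evaluations(
    records: Sequence[EvaluationRecord],
    rule: ConsensusRule = ConsensusRule.median_round_half_up,
) -> EvaluationRecord:
    """Collapse several evaluators' records for one item into a consensus record.

    The study's consensus was reached in a moderated discussion; this is
    the reproducible arithmetic stand-in.  Under the default rule every
    numeric field takes the per-field median, with half-integer medians
    rounded up (toward higher risk).  Narratives are concatenated.
    The result is permutation-invariant in its inputs.
    """
    if not records:
        raise ValueError("cannot consolidate an empty record set")
    first = records[0]
    for r in records[1:]:
        if r.item != first.item or r.flavour != first.flavour:
            raise ValueError("all records must describe the same item and flavour")

    def combine(values: Sequence[float], *, integer: bool = False) -> float:
        if rule == ConsensusRule.mean:
            out = float(np.mean(values))
        else:
            out = _median_half_up(values)
        if integer:
            out = float(_round_half_up(out))
        return out

    if first.flavour == "fire":
        narratives = " | ".join(
            r.ignition_narrative for r in records if r.ignition_narrative  # type: ignore[union-attr]
        )
        return FireEvaluation(
            item=first.item,
            evaluator_id=CONSENSUS_ID,
            contact=combine([r.contact for r in records]),
            junction_count=combine([r.junction_count for r in records], integer=True),
            ornateness=combine([r.ornateness for r in records]),
            reactive_capacity=combine([r.reactive_capacity for r in records]),
            combustible_volume=float(np.median([r.combustible_volume for r in records]))
            if rule == ConsensusRule.median_round_half_up
            else float(np.mean([r.combustible_volume for r in records])),
            ignition_narrative=narratives,
        )
    return ExposureEvaluation(
        item=first.item,
        evaluator_id=CONSENSUS_ID,
        child_use=combine([r.child_use for r in records]),
        bare_skin=combine([r.bare_skin for r in records]),
        mouthing=combine([r.mouthing for r in records]),
        cumulative_use=combine([r.cumulative_use for r in records]),
        surface_area=float(np.median([r.surface_area for r in records]))
        if rule == ConsensusRule.median_round_half_up
        else float(np.mean([r.surface_area for r in records])),
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

class Fixtures(NamedTuple):
    """Reference tables shipped with the package."""

    catalogue: list[FurnitureType]
    reference_scores: pd.DataFrame
    panel_comparison: pd.DataFrame
    reference_clusters: pd.DataFrame


def _data_path(name: str):
    return resources.files("fsmatrix.data").joinpath(name)


def _verified_bytes(name: str, checksums: dict[str, str]) -> bytes:
    raw = _data_path(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if checksums.get(name) != digest:
        raise FixtureIntegrityError(f"packaged fixture {name} failed checksum verification")
    return raw


def load_fixtures() -> Fixtures:
    """Load the packaged reference data, verifying checksums.

    Returns the 30-type catalogue (14 flagged as small-child products),
    the published per-type low/high/mean injury and exposure scores, the
    advisory-panel comparison records for the four-type subsample (with
    genuinely missing cells kept as missing, never zero), and the
    published dendrogram cluster memberships.
    """
    import io

    checksums = json.loads(_data_path("checksums.json").read_text())

    cat_df = pd.read_csv(io.BytesIO(_verified_bytes("catalogue.csv", checksums)), keep_default_na=False)
    catalogue = [
        FurnitureType(
            type_id=row.type_id,
            display_name=row.display_name,
            small_child_product=str(row.small_child_product).lower() == "true",
            notes=row.notes,
        )
        for row in cat_df.itertuples()
    ]
    ids = [t.type_id for t in catalogue]
    if len(set(ids)) != len(ids):
        raise FixtureIntegrityError("duplicate type_id in packaged catalogue")

    scores = pd.read_csv(io.BytesIO(_verified_bytes("reference_scores.csv", checksums)))
    panel = pd.read_csv(io.BytesIO(_verified_bytes("panel_comparison.csv", checksums)))
    clusters = pd.read_csv(io.BytesIO(_verified_bytes("reference_clusters.csv", checksums)))
    return Fixtures(catalogue, scores, panel, clusters)
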