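"""Synthetic catalogues and evaluator panels with known ground truth.

Real questionnaire data are the product of a small expert panel and
cannot ship with the package, so every pipeline stage is exercised on
synthetic data instead.  Product types are drawn from *archetypes* —
latent profiles capturing the contrasts seen in real catalogues: child
products score high on child use and mouthing but low on smoking-related
ignition contact; large resting furniture (armchairs, beds) is where
people smoke and sleep; small accessories sit low on most dimensions.
Evaluator scores are discretised Gaussian noise around the latent
profile, which reproduces the occasional low/high-variant inversion seen
in real panels.  The generator records the truth (archetype, latent
values, cluster label) separately; the scoring pipeline never sees it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogue import (
    ExposureEvaluation,
    FireEvaluation,
    FurnitureType,
    ItemVariant,
)

ORDINAL_CATEGORIES = (
    "contact", "ornateness", "reactive_capacity",
    "child_use", "bare_skin", "mouthing", "cumulative_use",
)

#: Narrative templates; the first mentions ignition-lexicon stems, the
#: second deliberately avoids every stem.
NARRATIVE_WITH_STEM = "A dropped cigarette or unattended candle could lodge against the upholstery."
NARRATIVE_WITHOUT_STEM = "Ignition considered plausible only from a nearby halogen heater or electrical fault."


@dataclass(frozen=True)
class ArchetypeProfile:
    """Latent profile from which one product type's items are generated.

    ``ordinal_means`` maps each Likert category to (low-variant,
    high-variant) latent means; the high-variant fire means are never
    below the low-variant ones.  Volume and surface ranges are per
    variant; ``p_ignition_mention`` is the probability a type's
    narrative mentions candles or smokers' materials.
    """

    name: str
    small_child: bool
    ordinal_means: dict[str, tuple[float, float]]
    junction_means: tuple[float, float]
    volume_range: tuple[tuple[float, float], tuple[float, float]]  # m^3, (low, high) variant
    surface_range: tuple[tuple[float, float], tuple[float, float]]  # m^2
    p_ignition_mention: float = 0.5

    def __post_init__(self):
        for cat, (lo, hi) in self.ordinal_means.items():
            if not (1 <= lo <= 5 and 1 <= hi <= 5):
                raise ValueError(f"{self.name}: latent mean for {cat} outside [1,5]")
            if cat in ("contact", "ornateness", "reactive_capacity") and hi < lo:
                raise ValueError(f"{self.name}: high-variant latent below low for {cat}")
        if not 0 <= self.p_ignition_mention <= 1:
            raise ValueError("p_ignition_mention must be a probability")
        for rng in (*self.volume_range, *self.surface_range):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"{self.name}: ranges must be positive and ordered")


def default_archetypes() -> dict[str, ArchetypeProfile]:
    """Three archetypes spanning the catalogue contrasts."""
    return {
        "child-product": ArchetypeProfile(
            name="child-product",
            small_child=True,
            ordinal_means={
                "contact": (1.5, 2.5), "ornateness": (2.0, 3.0), "reactive_capacity": (3.0, 4.0),
                "child_use": (4.5, 5.0), "bare_skin": (3.5, 4.0), "mouthing": (3.5, 4.5),
                "cumulative_use": (2.5, 3.5),
            },
            junction_means=(1.0, 3.0),
            volume_range=((0.001, 0.004), (0.003, 0.008)),
            surface_range=((0.3, 1.0), (0.8, 2.0)),
            p_ignition_mention=0.2,
        ),
        "resting-furniture": ArchetypeProfile(
            name="resting-furniture",
            small_child=False,
            ordinal_means={
                "contact": (3.0, 4.5), "ornateness": (2.5, 3.5), "reactive_capacity": (3.5, 4.5),
                "child_use": (1.5, 2.0), "bare_skin": (2.5, 3.0), "mouthing": (1.0, 1.5),
                "cumulative_use": (4.0, 4.5),
            },
            junction_means=(2.0, 4.0),
            volume_range=((0.01, 0.05), (0.05, 0.3)),
            surface_range=((2.0, 5.0), (4.0, 9.0)),
            p_ignition_mention=0.85,
        ),
        "small-accessory": ArchetypeProfile(
            name="small-accessory",
            small_child=False,
            ordinal_means={
                "contact": (2.0, 3.0), "ornateness": (1.5, 2.5), "reactive_capacity": (1.5, 2.5),
                "child_use": (1.5, 2.5), "bare_skin": (3.0, 3.5), "mouthing": (1.0, 2.0),
                "cumulative_use": (2.0, 3.0),
            },
            junction_means=(0.0, 1.5),
            volume_range=((0.001, 0.005), (0.004, 0.012)),
            surface_range=((0.1, 0.5), (0.4, 1.5)),
            p_ignition_mention=0.4,
        ),
    }


def generate_catalogue(
    n_types: int,
    archetype_mix: dict[str, float] | None = None,
    seed: int = 0,
    archetypes: dict[str, ArchetypeProfile] | None = None,
) -> tuple[list[FurnitureType], pd.DataFrame]:
    """Generate a catalogue of ``n_types`` product types with latent truth.

    ``archetype_mix`` gives sampling weights per archetype name (defaults
    to a uniform mix of the three built-ins).  Returns the catalogue and
    a truth table holding, per type, its archetype (= true cluster
    label), its per-category latent low/high means, the latent junction
    counts, exact combustible volumes and surface areas per variant, and
    whether its narrative mentions ignition-lexicon terms.  Same seed,
    same catalogue.
    """
    if n_types < 2:
        raise ValueError("n_types must be at least 2")
    archetypes = archetypes or default_archetypes()
    if archetype_mix is None:
        archetype_mix = {name: 1.0 for name in archetypes}
    if not archetype_mix:
        raise ValueError("archetype mix must be non-empty")
    unknown = set(archetype_mix) - set(archetypes)
    if unknown:
        raise ValueError(f"unknown archetype(s) in mix: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    names = sorted(archetype_mix)
    weights = np.array([archetype_mix[n] for n in names], dtype=float)
    weights /= weights.sum()

    catalogue: list[FurnitureType] = []
    truth_rows = []
    for i in range(n_types):
        arch = archetypes[names[rng.choice(len(names), p=weights)]]
        type_id = f"type_{i:03d}"
        catalogue.append(
            FurnitureType(
                type_id=type_id,
                display_name=f"Synthetic {arch.name} {i:03d}",
                small_child_product=arch.small_child,
                notes=f"archetype={arch.name}",
            )
        )
        row: dict[str, object] = {
            "type_id": type_id,
            "archetype": arch.name,
            "cluster_label": arch.name,
            "mentions_ignition": bool(rng.random() < arch.p_ignition_mention),
        }
        for cat, (lo, hi) in arch.ordinal_means.items():
            row[f"latent_{cat}_low"], row[f"latent_{cat}_high"] = lo, hi
        row["latent_junctions_low"], row["latent_junctions_high"] = arch.junction_means
        for variant, j in (("low", 0), ("high", 1)):
            row[f"volume_{variant}"] = float(rng.uniform(*arch.volume_range[j]))
            row[f"surface_area_{variant}"] = float(rng.uniform(*arch.surface_range[j]))
        truth_rows.append(row)
    return catalogue, pd.DataFrame(truth_rows)


def _discretise(rng: np.random.Generator, latent: float, noise_sd: float) -> int:
    value = latent + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return int(min(5, max(1, math.floor(value + 0.5))))


def generate_evaluations(
    catalogue: Sequence[FurnitureType],
    truth: pd.DataFrame,
    n_evaluators: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[list[FireEvaluation], list[ExposureEvaluation]]:
    """Simulate an evaluator panel filling both questionnaires.

    Ordinal answers are the latent mean plus Gaussian noise, rounded
    half-up and clamped to [1,5]; junction counts likewise (floored at
    0); volumes and areas get multiplicative log-normal noise around the
    item's exact latent value.  At ``noise_sd = 0`` every evaluator
    reproduces the latent profile exactly.
    """
    if n_evaluators < 1:
        raise ValueError("need at least one evaluator")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = truth.set_index("type_id")
    fire: list[FireEvaluation] = []
    exposure: list[ExposureEvaluation] = []
    for ftype in catalogue:
        row = t.loc[ftype.type_id]
        narrative = NARRATIVE_WITH_STEM if row["mentions_ignition"] else NARRATIVE_WITHOUT_STEM
        for variant in ("low", "high"):
            item = ItemVariant(type_id=ftype.type_id, variant=variant)
            for e in range(n_evaluators):
                ev_id = f"evaluator_{e + 1}"
                junctions = row[f"latent_junctions_{variant}"] + (
                    rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                )
                scale = math.exp(rng.normal(0.0, 0.2 * noise_sd)) if noise_sd > 0 else 1.0
                fire.append(
                    FireEvaluation(
                        item=item,
                        evaluator_id=ev_id,
                        contact=_discretise(rng, row[f"latent_contact_{variant}"], noise_sd),
                        junction_count=max(0, int(math.floor(junctions + 0.5))),
                        ornateness=_discretise(rng, row[f"latent_ornateness_{variant}"], noise_sd),
                        reactive_capacity=_discretise(rng, row[f"latent_reactive_capacity_{variant}"], noise_sd),
                        combustible_volume=float(row[f"volume_{variant}"]) * scale,
                        ignition_narrative=narrative,
                    )
                )
                scale_sa = math.exp(rng.normal(0.0, 0.2 * noise_sd)) if noise_sd > 0 else 1.0
                exposure.append(
                    ExposureEvaluation(
                        item=item,
                        evaluator_id=ev_id,
                        child_use=_discretise(rng, row[f"latent_child_use_{variant}"], noise_sd),
                        bare_skin=_discretise(rng, row[f"latent_bare_skin_{variant}"], noise_sd),
                        mouthing=_discretise(rng, row[f"latent_mouthing_{variant}"], noise_sd),
                        cumulative_use=_discretise(rng, row[f"latent_cumulative_use_{variant}"], noise_sd),
                        surface_area=float(row[f"surface_area_{variant}"]) * scale_sa,
                    )
                )
    return fire, exposure


def plant_clusters(
    k: int,
    separation: float,
    within_spread: float,
    n_per_cluster: int = 6,
    seed: int = 0,
    max_tries: int = 2000,
) -> pd.DataFrame:
    """Plant k well-separated clusters of per-type score triples.

    Cluster centroids are drawn in the [0,5]^3 score cube with pairwise
    Euclidean distance at least ``separation``; each of the
    ``n_per_cluster`` member types is the centroid plus isotropic
    Gaussian noise of sd ``within_spread``, clipped to the cube.
    Returns a summary-like frame (type_id, injury_mean, damage_mean,
    exposure_mean, cluster_label).  Raises when the requested geometry
    cannot be placed inside the cube.
    """
    if k < 2:
        raise ValueError("need at least two clusters")
    if separation <= 0 or within_spread < 0:
        raise ValueError("separation must be positive and within_spread non-negative")
    if separation > math.sqrt(3) * 5:
        raise ValueError("separation exceeds the diameter of the [0,5]^3 score cube")
    rng = np.random.default_rng(seed)
    centroids: list[np.ndarray] = []
    tries = 0
    while len(centroids) < k:
        cand = rng.uniform(0.0, 5.0, size=3)
        if all(np.linalg.norm(cand - c) >= separation for c in centroids):
            centroids.append(cand)
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {k} centroids at separation {separation} within [0,5]^3"
            )
    rows = []
    for ci, centre in enumerate(centroids):
        for j in range(n_per_cluster):
            point = np.clip(centre + rng.normal(0.0, within_spread, size=3), 0.0, 5.0)
            rows.append(
                {
                    "type_id": f"planted_{ci}_{j}",
                    "injury_mean": float(point[0]),
                    "damage_mean": float(point[1]),
                    "exposure_mean": float(point[2]),
                    "cluster_label": f"cluster_{ci}",
                }
            )
    return pd.DataFrame(rows)
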