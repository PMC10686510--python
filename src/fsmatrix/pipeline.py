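"""End-to-end orchestration: questionnaires in, scored artefacts out.

``run_pipeline`` ties the stages together: consolidate raw evaluator
records per item, score both models, summarise per type, classify
quadrants, cluster, run the sensitivity sweep, and write every artefact
(CSV tables, Newick tree, figures, JSON run log) under one output
directory.  Reruns with the same configuration produce byte-identical
CSV output.
"""

from __future__ import annotations

import hashlib
import json
import platform
from collections import defaultdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .catalogue import (
    CONSENSUS_ID,
    EvaluationRecord,
    ExposureEvaluation,
    FireEvaluation,
    ItemScores,
    consolidate_evaluations,
    read_evaluations,
    write_scores,
)
from .config import PipelineConfig, ThresholdConfig
from .exposure import exposure_score
from .fire import damage_risk_score, injury_risk_score
from .reconcile import (
    build_dendrogram,
    cluster_assignments,
    distance_matrix,
    quadrant_classify,
    summarise_scores,
    to_newick,
)
from .sensitivity import sensitivity_sweep


def consolidate_by_item(records: Sequence[EvaluationRecord], config: ThresholdConfig) -> list[EvaluationRecord]:
    """Collapse multi-evaluator records into one consensus record per item.

    Records already marked as consensus pass through untouched.  Input
    order of first appearance is preserved.
    """
    grouped: dict[tuple[str, str], list[EvaluationRecord]] = defaultdict(list)
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.item.type_id, rec.item.variant)
        if key not in grouped:
            order.append(key)
        grouped[key].append(rec)
    out: list[EvaluationRecord] = []
    for key in order:
        group = grouped[key]
        if len(group) == 1 and group[0].evaluator_id == CONSENSUS_ID:
            out.append(group[0])
        else:
            out.append(consolidate_evaluations(group, config.consensus_rule))
    return out


def score_items(
    fire: Sequence[FireEvaluation],
    exposure: Sequence[ExposureEvaluation],
    config: ThresholdConfig | None = None,
) -> list[ItemScores]:
    """Consolidate and score every item present in both questionnaires."""
    cfg = config or ThresholdConfig()
    fire_c = {(r.item.type_id, r.item.variant): r for r in consolidate_by_item(fire, cfg)}
    expo_c = {(r.item.type_id, r.item.variant): r for r in consolidate_by_item(exposure, cfg)}
    missing = set(fire_c) ^ set(expo_c)
    if missing:
        raise ValueError(f"items present in only one questionnaire: {sorted(missing)}")
    return [
        ItemScores(
            type_id=type_id,
            variant=variant,  # type: ignore[arg-type]
            injury_risk=injury_risk_score(fire_c[(type_id, variant)], cfg),
            damage_risk=damage_risk_score(fire_c[(type_id, variant)], cfg),
            exposure_score=exposure_score(expo_c[(type_id, variant)], cfg),
        )
        for type_id, variant in sorted(fire_c)
    ]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write artefacts under ``config.output_dir``.

    Returns a mapping of artefact names to paths.  Raises with a
    stage-labelled message if any stage fails.
    """
    cfg = config.thresholds
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, Path] = {}

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
                return False

        return _Stage()

    with stage("read"):
        if config.fire_input is None or config.exposure_input is None:
            raise ValueError("both fire_input and exposure_input are required")
        fire = read_evaluations(config.fire_input, "fire")
        expo = read_evaluations(config.exposure_input, "exposure")

    with stage("score"):
        scores = score_items(fire, expo, cfg)
        artefacts["scores"] = out / "scores.csv"
        write_scores(scores, artefacts["scores"])

    with stage("summarise"):
        summary = summarise_scores(scores)
        quadrants = quadrant_classify(summary, rule=cfg.quadrant_threshold_rule)

    with stage("cluster"):
        tree = build_dendrogram(
            distance_matrix(summary), cfg.linkage_method, labels=list(summary["type_id"])
        )
        assignments = cluster_assignments(tree, cfg.cut_height)
        summary["quadrant"] = summary["type_id"].map(quadrants)
        summary["cluster_id"] = summary["type_id"].map(assignments)
        artefacts["summary"] = out / "summary.csv"
        summary.to_csv(artefacts["summary"], index=False, float_format="%.6f")
        artefacts["tree"] = out / "clusters.nwk"
        artefacts["tree"].write_text(to_newick(tree) + "\n", encoding="utf-8")

    with stage("sensitivity"):
        consolidated_fire = [
            r for r in consolidate_by_item(fire, cfg) if isinstance(r, FireEvaluation)
        ]
        sweep = sensitivity_sweep(consolidated_fire, config=cfg, seed=config.seed)
        artefacts["sensitivity"] = out / "sensitivity.csv"
        sweep.to_csv(artefacts["sensitivity"], index=False, float_format="%.6f")

    if config.make_figures:
        with stage("figures"):
            from . import plotting

            artefacts["fig_ranking_injury"] = plotting.ranked_bar(
                summary, "injury", out / "ranking_injury.png"
            )
            artefacts["fig_ranking_exposure"] = plotting.ranked_bar(
                summary, "exposure", out / "ranking_exposure.png"
            )
            artefacts["fig_scatter"] = plotting.scatter_with_ellipses(
                summary, out / "scatter_quadrants.png", rule=cfg.quadrant_threshold_rule
            )
            artefacts["fig_dendrogram"] = plotting.dendrogram_figure(
                tree, cfg.cut_height, out / "dendrogram.png"
            )
            artefacts["fig_sensitivity"] = plotting.sensitivity_jitter_plot(
                sweep, out / "sensitivity_jitter.png"
            )

    with stage("log"):
        cfg_json = config.model_dump_json()
        artefacts["run_log"] = out / "run_log.json"
        artefacts["run_log"].write_text(
            json.dumps(
                {
                    "package_version": __version__,
                    "python": platform.python_version(),
                    "seed": config.seed,
                    "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                    "config": json.loads(cfg_json),
                    "n_items": len(scores),
                    "n_types": int(summary.shape[0]),
                },
                indent=2,
                default=str,
            )
            + "\n",
            encoding="utf-8",
        )

    return artefacts
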