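"""Reconcile fire-risk and exposure scores: summaries, rankings, quadrants, clusters.

Each product type is summarised by the mean and range of its low- and
high-risk variant scores.  Types are then ranked per score, placed in a
fire-risk x exposure scatter (with low/high ranges drawn as ellipses and
relative thresholds dividing the plane into quadrants; the upper-left
quadrant — low fire risk, high exposure potential — is the
policy-relevant region), and clustered agglomeratively on the Euclidean
distance in (injury, damage, exposure) space, with a horizontal
dendrogram cut separating multi-member clusters from singleton outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .catalogue import ItemScores
from .config import LinkageMethod, QuadrantRule, ThresholdConfig
from .errors import ValidationError

SUMMARY_COLUMNS = [
    "type_id",
    "injury_low", "injury_high", "injury_mean",
    "damage_low", "damage_high", "damage_mean",
    "exposure_low", "exposure_high", "exposure_mean",
]

RANK_KEYS = ("injury_mean", "damage_mean", "exposure_mean")


def type_summary(low_score: float, high_score: float) -> tuple[float, float, float]:
    """Mean and range endpoints of a low/high variant pair.

    Inversions (low scoring above high) are legitimate and preserved:
    the mean and min/max are computed over the pair as given.
    """
    if not (np.isfinite(low_score) and np.isfinite(high_score)):
        raise ValidationError("variant scores must be finite")
    return ((low_score + high_score) / 2.0, min(low_score, high_score), max(low_score, high_score))


def summarise_scores(scores: Sequence[ItemScores]) -> pd.DataFrame:
    """Collapse per-variant scores into one summary row per product type."""
    df = pd.DataFrame([s.__dict__ for s in scores])
    rows = []
    for type_id, grp in df.groupby("type_id", sort=True):
        byv = grp.set_index("variant")
        if set(byv.index) != {"low", "high"}:
            raise ValidationError(f"type {type_id} must have exactly one low and one high variant")
        row: dict[str, object] = {"type_id": type_id}
        for col, prefix in [("injury_risk", "injury"), ("damage_risk", "damage"), ("exposure_score", "exposure")]:
            lo, hi = float(byv.loc["low", col]), float(byv.loc["high", col])
            mean, _, _ = type_summary(lo, hi)
            row[f"{prefix}_low"], row[f"{prefix}_high"], row[f"{prefix}_mean"] = lo, hi, mean
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def rank_types(summaries: pd.DataFrame, key: str = "injury_mean", ascending: bool = False) -> list[str]:
    """Rank type_ids by a summary column, descending by default.

    Ties occupy consecutive positions ordered lexicographically by
    type_id, so rankings are deterministic.
    """
    if key not in RANK_KEYS:
        raise KeyError(f"unknown ranking key {key!r}; expected one of {RANK_KEYS}")
    if summaries.empty:
        raise ValueError("cannot rank an empty summary table")
    ordered = summaries.sort_values([key, "type_id"], ascending=[ascending, True], kind="mergesort")
    return list(ordered["type_id"])


def top_k_membership(ranking: Sequence[str], subset: Iterable[str], k: int) -> int:
    """Count how many subset members fall in the first k ranked positions."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds catalogue size {len(ranking)}")
    subset = set(subset)
    return sum(1 for t in ranking[:k] if t in subset)


DEFAULT_COORDS = ("injury_mean", "damage_mean", "exposure_mean")


def distance_matrix(points: pd.DataFrame | np.ndarray,
                    coords: Sequence[str] = DEFAULT_COORDS) -> np.ndarray:
    """Pairwise Euclidean distances over per-type score coordinates.

    ``points`` is an (n, d) array or a summary DataFrame, in which case
    the ``coords`` columns (by default the injury, damage and exposure
    means) are used.
    """
    if isinstance(points, pd.DataFrame):
        points = points[list(coords)].to_numpy()
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two points in a 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite coordinate in distance computation")
    return squareform(pdist(arr, metric="euclidean"))


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge tree over product-type leaves.

    ``merges`` is the scipy linkage matrix: row i merges nodes
    ``merges[i, 0]`` and ``merges[i, 1]`` (indices < n are leaves) at
    height ``merges[i, 2]``; there are n - 1 merges for n leaves.
    """

    labels: tuple[str, ...]
    merges: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def build_dendrogram(dist: np.ndarray, linkage: LinkageMethod | str = LinkageMethod.average,
                     labels: Sequence[str] | None = None) -> ClusterTree:
    """Agglomerative clustering of a symmetric distance matrix."""
    linkage = LinkageMethod(linkage)
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    n = dist.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")
    condensed = squareform(dist, checks=True)
    merges = hierarchy.linkage(condensed, method=linkage.value)
    return ClusterTree(labels=tuple(labels), merges=merges)


def cut_clusters(tree: ClusterTree, height: float) -> tuple[list[list[str]], list[str]]:
    """Cut the dendrogram at a height.

    Leaves joined by merges *strictly below* the cut form clusters
    (two or more members); leaves taking part in no sub-height merge are
    outliers.  Returns ``(clusters, outliers)`` with clusters ordered by
    their lexicographically first member and members sorted.
    """
    if height < 0:
        raise ValueError("cut height must be non-negative")
    n = tree.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, h, _) in enumerate(tree.merges):
        if h < height:
            node = n + i
            parent[find(int(a))] = node
            parent[find(int(b))] = node

    groups: dict[int, list[str]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(tree.labels[leaf])
    clusters = sorted((sorted(g) for g in groups.values() if len(g) > 1), key=lambda g: g[0])
    outliers = sorted(g[0] for g in groups.values() if len(g) == 1)
    return clusters, outliers


def cluster_assignments(tree: ClusterTree, height: float) -> dict[str, str]:
    """Map each type_id to a cluster id ('c1', 'c2', ...) or 'outlier'."""
    clusters, outliers = cut_clusters(tree, height)
    out = {label: f"c{i + 1}" for i, members in enumerate(clusters) for label in members}
    out.update({label: "outlier" for label in outliers})
    return out


def to_newick(tree: ClusterTree) -> str:
    """Export the merge tree as a Newick string.

    Branch lengths are differences in merge height, so the root-to-leaf
    path length of every leaf equals the root merge height (ultrametric
    for monotone linkages).
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for i, (_, _, h, _) in enumerate(tree.merges):
        heights[n + i] = float(h)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            return f"{tree.labels[node]}:{length:.12g}"
        a, b = int(tree.merges[node - n, 0]), int(tree.merges[node - n, 1])
        own = heights[node]
        return f"({render(a, own)},{render(b, own)}):{length:.12g}"

    root = 2 * n - 2
    a, b = int(tree.merges[-1, 0]), int(tree.merges[-1, 1])
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"


QUADRANTS = ("upper-left", "upper-right", "lower-left", "lower-right")


def quadrant_thresholds(summaries: pd.DataFrame,
                        rule: QuadrantRule = QuadrantRule.midrange,
                        explicit: tuple[float, float] | None = None) -> tuple[float, float]:
    """Derive the (injury, exposure) thresholds of the quadrant plot."""
    x = summaries["injury_mean"].to_numpy(float)
    y = summaries["exposure_mean"].to_numpy(float)
    rule = QuadrantRule(rule)
    if rule == QuadrantRule.explicit:
        if explicit is None:
            raise ValueError("explicit quadrant rule requires threshold values")
        return explicit
    if rule == QuadrantRule.median:
        return float(np.median(x)), float(np.median(y))
    if x.min() == x.max() or y.min() == y.max():
        raise ValueError("midrange thresholds are undefined for a degenerate axis")
    return (float((x.min() + x.max()) / 2), float((y.min() + y.max()) / 2))


def quadrant_classify(summaries: pd.DataFrame,
                      thresholds: tuple[float, float] | None = None,
                      rule: QuadrantRule = QuadrantRule.midrange) -> dict[str, str]:
    """Label each type by its quadrant in the injury x exposure plane.

    Boundary convention: a point exactly on the x threshold counts as
    right, exactly on the y threshold as upper.
    """
    if thresholds is None:
        thresholds = quadrant_thresholds(summaries, rule)
    x_thr, y_thr = thresholds
    labels = {}
    for row in summaries.itertuples():
        horiz = "right" if row.injury_mean >= x_thr else "left"
        vert = "upper" if row.exposure_mean >= y_thr else "lower"
        labels[row.type_id] = f"{vert}-{horiz}"
    return labels


@dataclass(frozen=True)
class EllipseGlyph:
    """Scatter-plot glyph: centred on the mean, semi-axes span the low/high range."""

    center: tuple[float, float]
    semi_axis_x: float
    semi_axis_y: float


def ellipse_params(summary_row: Mapping[str, float] | pd.Series) -> EllipseGlyph:
    return EllipseGlyph(
        center=(float(summary_row["injury_mean"]), float(summary_row["exposure_mean"])),
        semi_axis_x=abs(summary_row["injury_high"] - summary_row["injury_low"]) / 2.0,
        semi_axis_y=abs(summary_row["exposure_high"] - summary_row["exposure_low"]) / 2.0,
    )


def reproduce_reference_clusters(points: pd.DataFrame,
                                 reference: pd.DataFrame,
                                 cut_height: float = 0.56,
                                 linkages: Sequence[LinkageMethod] = tuple(LinkageMethod),
                                 coords: Sequence[str] = DEFAULT_COORDS,
                                 ) -> pd.DataFrame:
    """Validation experiment: cluster score coordinates under each linkage
    and report agreement with a published reference partition.

    ``points`` is a summary DataFrame; ``reference`` has columns
    ``type_id`` and ``cluster`` (singletons marked 'outlier').  Agreement
    is the adjusted Rand index with every outlier treated as its own
    singleton group.  Returns one row per linkage with the ARI, the
    number of multi-member clusters and the number of outliers.
    """
    from sklearn.metrics import adjusted_rand_score

    ref = reference.set_index("type_id")["cluster"]
    # give each reference outlier a unique label so singletons never pool
    ref_labels = {
        t: (f"outlier_{t}" if str(c) == "outlier" else str(c)) for t, c in ref.items()
    }
    labels = list(points["type_id"])
    dist = distance_matrix(points, coords)
    rows = []
    for linkage in linkages:
        linkage = LinkageMethod(linkage)
        tree = build_dendrogram(dist, linkage, labels=labels)
        assign = cluster_assignments(tree, cut_height)
        got = [assign[t] if assign[t] != "outlier" else f"outlier_{t}" for t in labels]
        want = [ref_labels[t] for t in labels]
        clusters, outliers = cut_clusters(tree, cut_height)
        rows.append(
            {
                "linkage": linkage.value,
                "ari": adjusted_rand_score(want, got),
                "n_clusters": len(clusters),
                "n_outliers": len(outliers),
            }
        )
    return pd.DataFrame(rows).sort_values("ari", ascending=False).reset_index(drop=True)
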