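"""Type summaries, rankings, distances, dendrogram cuts and quadrants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fsmatrix.catalogue import ItemScores
from fsmatrix.config import LinkageMethod, QuadrantRule
from fsmatrix.errors import ValidationError
from fsmatrix.reconcile import (
    build_dendrogram,
    cluster_assignments,
    cut_clusters,
    distance_matrix,
    ellipse_params,
    quadrant_classify,
    quadrant_thresholds,
    rank_types,
    summarise_scores,
    to_newick,
    top_k_membership,
    type_summary,
)


def summary_frame(rows):
    cols = ["type_id", "injury_mean", "damage_mean", "exposure_mean"]
    df = pd.DataFrame(rows, columns=cols)
    for prefix in ("injury", "damage", "exposure"):
        df[f"{prefix}_low"] = df[f"{prefix}_mean"]
        df[f"{prefix}_high"] = df[f"{prefix}_mean"]
    return df


class TestTypeSummary:
    def test_car_seat_mean(self):
        mean, lo, hi = type_summary(1.88, 2.00)
        assert mean == pytest.approx(1.94) and (lo, hi) == (1.88, 2.00)

    def test_inverted_pair_preserved(self):
        mean, lo, hi = type_summary(4.20, 3.20)
        assert mean == pytest.approx(3.70) and (lo, hi) == (3.20, 4.20)

    def test_degenerate_pair(self):
        assert type_summary(2.5, 2.5) == (2.5, 2.5, 2.5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            type_summary(float("nan"), 2.0)


class TestSummariseScores:
    def test_collapses_variant_pairs(self):
        scores = [
            ItemScores("a", "low", 1.0, 1.5, 2.0),
            ItemScores("a", "high", 3.0, 2.5, 4.0),
            ItemScores("b", "low", 2.0, 2.0, 2.0),
            ItemScores("b", "high", 2.0, 2.0, 2.0),
        ]
        df = summarise_scores(scores).set_index("type_id")
        assert df.loc["a", "injury_mean"] == 2.0
        assert df.loc["a", "exposure_mean"] == 3.0
        assert df.loc["b", "damage_mean"] == 2.0

    def test_missing_variant_rejected(self):
        with pytest.raises(ValidationError):
            summarise_scores([ItemScores("a", "low", 1, 1, 1)])


class TestRanking:
    def test_single_summary(self):
        df = summary_frame([("only", 2, 2, 2)])
        assert rank_types(df, "injury_mean") == ["only"]

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            rank_types(summary_frame([("a", 1, 1, 1)]), "charm_mean")

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(13)
        rows = [(f"t{i}", v, v, v) for i, v in enumerate(rng.uniform(1, 5, 20))]
        df = summary_frame(rows)
        oracle = [t for t, v, _, _ in sorted(rows, key=lambda r: (-r[1], r[0]))]
        assert rank_types(df, "injury_mean") == oracle

    def test_ties_break_lexicographically(self):
        df = summary_frame([("zeta", 3, 3, 3), ("alpha", 3, 3, 3), ("mid", 4, 4, 4)])
        assert rank_types(df, "injury_mean") == ["mid", "alpha", "zeta"]


class TestTopK:
    def test_empty_subset(self):
        assert top_k_membership(["a", "b"], set(), 2) == 0

    def test_k_larger_than_catalogue_rejected(self):
        with pytest.raises(ValueError):
            top_k_membership(["a"], {"a"}, 2)

    def test_full_k_counts_whole_intersection(self):
        ranking = ["a", "b", "c", "d"]
        subset = {"b", "d", "x"}
        assert top_k_membership(ranking, subset, 4) == 2

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        types = [f"t{i}" for i in range(6)]
        for _ in range(20):
            ranking = list(rng.permutation(types))
            subset = {t for t in types if rng.random() < 0.5}
            for k in range(7):
                brute = sum(t in subset for t in ranking[:k])
                assert top_k_membership(ranking, subset, k) == brute


class TestDistanceMatrix:
    def test_identical_points_give_zero(self):
        d = distance_matrix(np.zeros((2, 3)))
        assert d[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        d = distance_matrix(np.array([[0, 0, 0], [3, 4, 0]], dtype=float))
        assert d[0, 1] == pytest.approx(5.0)

    def test_matches_pairwise_norm_oracle(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 5, (5, 3))
        d = distance_matrix(pts)
        for i, j in itertools.combinations(range(5), 2):
            assert d[i, j] == pytest.approx(np.sqrt(((pts[i] - pts[j]) ** 2).sum()), abs=1e-12)
            assert d[i, j] == d[j, i]
        assert np.all(np.diag(d) == 0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(23)
        d = distance_matrix(rng.uniform(0, 5, (8, 3)))
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_nonfinite_coordinate_rejected(self):
        with pytest.raises(ValidationError):
            distance_matrix(np.array([[0.0, 0.0, np.inf], [1, 1, 1]]))


class TestDendrogram:
    def test_two_points_merge_at_their_distance(self):
        d = distance_matrix(np.array([[0.0, 0, 0], [3, 4, 0]]))
        tree = build_dendrogram(d, "single", labels=["a", "b"])
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(5.0)

    def test_collinear_points_first_merge(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [10, 0, 0]])
        tree = build_dendrogram(distance_matrix(pts), LinkageMethod.single)
        assert tree.merges[0, 2] == pytest.approx(1.0)

    def test_n_minus_one_merges(self):
        rng = np.random.default_rng(2)
        for n in (2, 5, 9):
            tree = build_dendrogram(distance_matrix(rng.uniform(0, 5, (n, 3))), "average")
            assert tree.merges.shape[0] == n - 1
            assert tree.n_leaves == n

    def test_unknown_linkage_rejected(self):
        d = distance_matrix(np.eye(3))
        with pytest.raises(ValueError):
            build_dendrogram(d, "centroidal-vibes")


class TestCutClusters:
    @pytest.fixture
    def blob_tree(self):
        rng = np.random.default_rng(31)
        a = rng.normal(0, 0.05, (5, 3)) + [1, 1, 1]
        b = rng.normal(0, 0.05, (5, 3)) + [4, 4, 4]
        pts = np.vstack([a, b])
        labels = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        return build_dendrogram(distance_matrix(pts), "average", labels=labels)

    def test_cut_at_zero_gives_all_outliers(self, blob_tree):
        clusters, outliers = cut_clusters(blob_tree, 0.0)
        assert clusters == [] and len(outliers) == 10

    def test_cut_above_root_gives_one_cluster(self, blob_tree):
        root = blob_tree.merges[-1, 2]
        clusters, outliers = cut_clusters(blob_tree, root + 1)
        assert len(clusters) == 1 and len(clusters[0]) == 10 and outliers == []

    def test_two_planted_blobs_recovered_at_intermediate_cut(self, blob_tree):
        clusters, outliers = cut_clusters(blob_tree, 1.0)
        assert len(clusters) == 2 and outliers == []
        assert {frozenset(c) for c in clusters} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_partition_covers_all_leaves_at_every_height(self, blob_tree):
        heights = [0.0, 0.1, 0.5, 1.0, 3.0, 10.0]
        for h in heights:
            clusters, outliers = cut_clusters(blob_tree, h)
            members = [m for c in clusters for m in c] + outliers
            assert sorted(members) == sorted(blob_tree.labels)

    def test_negative_height_rejected(self, blob_tree):
        with pytest.raises(ValueError):
            cut_clusters(blob_tree, -0.1)


class TestNewick:
    def test_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(37)
        labels = [f"t{i}" for i in range(6)]
        tree = build_dendrogram(distance_matrix(rng.uniform(0, 5, (6, 3))), "average", labels=labels)
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(labels)
        # ultrametric: every root-to-leaf path equals the root merge height
        root_height = tree.merges[-1, 2]
        for leaf in parsed.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_height, abs=1e-6)


class TestQuadrants:
    def test_extreme_corner_is_upper_left(self):
        df = summary_frame([("lo_hi", 1, 1, 5), ("hi_lo", 5, 5, 1)])
        labels = quadrant_classify(df)
        assert labels["lo_hi"] == "upper-left" and labels["hi_lo"] == "lower-right"

    def test_boundary_point_counts_upper_right(self):
        df = summary_frame([("a", 1, 1, 1), ("b", 5, 5, 5), ("edge", 3, 3, 3)])
        labels = quadrant_classify(df, thresholds=(3.0, 3.0))
        assert labels["edge"] == "upper-right"

    def test_matches_sign_oracle_and_counts_sum(self):
        rng = np.random.default_rng(41)
        rows = [(f"t{i}", x, x, y) for i, (x, y) in enumerate(rng.uniform(1, 5, (30, 2)))]
        df = summary_frame(rows)
        x_thr, y_thr = quadrant_thresholds(df)
        labels = quadrant_classify(df)
        counts = {q: 0 for q in ("upper-left", "upper-right", "lower-left", "lower-right")}
        for tid, x, _, y in rows:
            want = ("upper" if y >= y_thr else "lower") + "-" + ("right" if x >= x_thr else "left")
            assert labels[tid] == want
            counts[want] += 1
        assert sum(counts.values()) == 30

    def test_degenerate_axis_rejected_under_midrange(self):
        df = summary_frame([("a", 2, 2, 1), ("b", 2, 2, 4)])
        with pytest.raises(ValueError):
            quadrant_thresholds(df, QuadrantRule.midrange)


class TestEllipse:
    def test_pillow_row(self):
        row = {"injury_mean": 2.44, "injury_low": 2.00, "injury_high": 2.88,
               "exposure_mean": 3.70, "exposure_low": 4.20, "exposure_high": 3.20}
        g = ellipse_params(row)
        assert g.center == (2.44, 3.70)
        assert g.semi_axis_y == pytest.approx(0.50)

    def test_zero_range_gives_zero_axes(self):
        row = {"injury_mean": 2.0, "injury_low": 2.0, "injury_high": 2.0,
               "exposure_mean": 3.0, "exposure_low": 3.0, "exposure_high": 3.0}
        g = ellipse_params(row)
        assert g.semi_axis_x == 0 and g.semi_axis_y == 0

    def test_swap_invariance(self):
        a = ellipse_params({"injury_mean": 2, "injury_low": 1, "injury_high": 3,
                            "exposure_mean": 2, "exposure_low": 1, "exposure_high": 3})
        b = ellipse_params({"injury_mean": 2, "injury_low": 3, "injury_high": 1,
                            "exposure_mean": 2, "exposure_low": 3, "exposure_high": 1})
        assert a == b


class TestClusterAssignments:
    def test_labels_cover_every_type(self):
        rng = np.random.default_rng(43)
        pts = rng.uniform(0, 5, (12, 3))
        labels = [f"t{i}" for i in range(12)]
        tree = build_dendrogram(distance_matrix(pts), "average", labels=labels)
        assign = cluster_assignments(tree, 1.0)
        assert set(assign) == set(labels)
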