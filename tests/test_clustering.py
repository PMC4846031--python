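"""Incidence vectors, validity grids, monotone pruning, and k selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from comorbnet.clustering import (
    ValidityGrid,
    build_vectors,
    choose_clusters,
    cluster_profiles,
    cluster_solutions,
    remove_monotonic,
    score_grid,
    select_k,
)
from comorbnet.ingest import N_AGE_BINS, OnsetHistogramSet
from conftest import planted_histograms


def hist(values) -> np.ndarray:
    out = np.zeros(N_AGE_BINS, dtype=int)
    for age, count in values.items():
        out[age] = count
    return out


class TestBuildVectors:
    def test_three_four_five_triangle(self):
        vectors = build_vectors(OnsetHistogramSet({"d": hist({0: 3, 1: 4})}))
        assert vectors.loc["d", 0] == pytest.approx(0.6)
        assert vectors.loc["d", 1] == pytest.approx(0.8)
        assert vectors.loc["d", 2:].sum() == 0

    def test_unit_norm_for_random_histograms(self):
        rng = np.random.default_rng(1)
        hists = OnsetHistogramSet({f"d{i}": rng.integers(0, 50, N_AGE_BINS) + 1 for i in range(20)})
        norms = np.linalg.norm(build_vectors(hists).to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_zero_histogram_errors_naming_disease(self):
        with pytest.raises(ValueError, match="ghost"):
            build_vectors(OnsetHistogramSet({"ghost": np.zeros(N_AGE_BINS, int)}))


def two_group_vectors(n_per_group=6, jitter=0.0, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = {}
    for g, center in enumerate((10, 70)):
        base = np.exp(-0.5 * ((np.arange(N_AGE_BINS) - center) / 4.0) ** 2)
        for i in range(n_per_group):
            v = base + jitter * rng.random(N_AGE_BINS)
            rows[f"g{g}_{i}"] = v / np.linalg.norm(v)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=range(N_AGE_BINS))
    frame.index.name = "disease"
    return frame


class TestClusterSolutions:
    def test_separable_groups_recovered_by_every_method(self):
        vectors = two_group_vectors(jitter=0.01)
        truth = [0] * 6 + [1] * 6
        for (method, k), labels in cluster_solutions(vectors, k_range=[2]).items():
            assert adjusted_rand_score(truth, labels) == 1.0, method

    def test_k_equal_n_gives_singletons(self):
        vectors = two_group_vectors(n_per_group=3, jitter=0.05)
        labels = cluster_solutions(vectors, methods=["ward"], k_range=[6])[("ward", 6)]
        assert len(set(labels)) == 6

    def test_k_exceeding_n_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_solutions(two_group_vectors(n_per_group=2), k_range=[5])

    def test_planted_profiles_recovered_by_ward(self):
        rng = np.random.default_rng(4)
        hists, truth = planted_histograms(24, centers=(10, 35, 60, 82), rng=rng, n_onsets=600)
        vectors = build_vectors(hists)
        labels = cluster_solutions(vectors, methods=["ward"], k_range=[4])[("ward", 4)]
        assert adjusted_rand_score([truth[d] for d in vectors.index], labels) == 1.0


class TestScoreGrid:
    def test_perfect_separation_maxes_silhouette(self):
        vectors = two_group_vectors(jitter=0.0)  # duplicate points within groups
        labelings = {("ward", 2): np.array([0] * 6 + [1] * 6)}
        grid = score_grid(labelings, vectors, measures=["silhouette"])
        assert grid.scores.loc[("ward", 2), "silhouette"] == pytest.approx(1.0)

    def test_degenerate_labeling_marked_failed_not_dropped(self):
        vectors = two_group_vectors(jitter=0.01)
        labelings = {("ward", 1): np.zeros(12, dtype=int)}
        grid = score_grid(labelings, vectors, measures=["silhouette", "dunn"])
        assert grid.scores.isna().all().all()  # marked NaN, cells still present

    def test_planted_labels_beat_random_on_every_measure(self):
        rng = np.random.default_rng(8)
        hists, truth = planted_histograms(24, centers=(10, 40, 75), rng=rng, n_onsets=600)
        vectors = build_vectors(hists)
        planted = np.array([truth[d] for d in vectors.index])
        random = rng.permutation(planted)
        grid = score_grid(
            {("ward", 3): planted, ("kmeans", 3): random}, vectors, seed=8
        )
        better = grid.scores.loc[("ward", 3)] > grid.scores.loc[("kmeans", 3)]
        assert better.all(), grid.scores

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="unknown measures"):
            score_grid({}, two_group_vectors(), measures=["bogus"])


def synthetic_grid(scores_by_measure: dict[str, dict[str, list[float]]], ks) -> ValidityGrid:
    """Grid from per-measure, per-method score sequences over ks."""
    methods = sorted(next(iter(scores_by_measure.values())))
    index = pd.MultiIndex.from_product([methods, ks], names=["method", "k"])
    data = {
        m: [per_method[method][i] for method in methods for i in range(len(ks))]
        for m, per_method in scores_by_measure.items()
    }
    return ValidityGrid(
        pd.DataFrame(data, index=index), tuple(ks), tuple(methods), tuple(scores_by_measure)
    )


class TestRemoveMonotonic:
    ks = [2, 3, 4, 5]

    def test_measure_scoring_exactly_k_removed(self):
        grid = synthetic_grid(
            {
                "is_k": {"ward": [2, 3, 4, 5], "kmeans": [2, 3, 4, 5]},
                "peaked": {"ward": [0, 1, 0.5, 0.2], "kmeans": [0, 1, 0.4, 0.1]},
            },
            self.ks,
        )
        pruned, removed = remove_monotonic(grid)
        assert removed == ["is_k"] and pruned.measures == ("peaked",)

    def test_interior_peak_for_one_method_retains_measure(self):
        grid = synthetic_grid(
            {"m": {"ward": [1, 2, 3, 4], "kmeans": [1, 5, 3, 2]}}, self.ks
        )
        _, removed = remove_monotonic(grid)
        assert removed == []

    def test_exactly_the_monotone_measures_removed(self):
        per_method = lambda seq: {"ward": seq, "kmeans": seq}
        grid = synthetic_grid(
            {
                "up": per_method([1, 2, 3, 4]),
                "down": per_method([4, 3, 2, 1]),
                "up2": per_method([0.1, 0.2, 0.3, 0.9]),
                "peak": per_method([0, 2, 1, 0.5]),
                "valley": per_method([2, 0, 1, 3]),
                "plateau": per_method([1, 2, 2, 3]),
            },
            self.ks,
        )
        _, removed = remove_monotonic(grid)
        assert sorted(removed) == ["down", "up", "up2"]

    def test_all_monotone_errors(self):
        grid = synthetic_grid({"m": {"ward": [1, 2, 3, 4], "kmeans": [2, 3, 4, 5]}}, self.ks)
        with pytest.raises(ValueError, match="monotone"):
            remove_monotonic(grid)


def fake_labelings(vectors, ks):
    rng = np.random.default_rng(0)
    out = {}
    for k in ks:
        labels = np.arange(len(vectors)) % k
        out[("ward", k)] = labels
    return out


class TestSelectK:
    def composite_grid(self, values, ks):
        return synthetic_grid({"m": {"ward": list(values)}}, ks)

    def test_interior_peak_chosen(self):
        ks = [2, 3, 4, 5, 6]
        grid = self.composite_grid([-1.0, 0.2, 0.9, 0.4, 0.1], ks)
        vectors = two_group_vectors(n_per_group=5, jitter=0.02)
        sel = select_k(grid, fake_labelings(vectors, ks), vectors)
        assert sel.chosen_k == 4
        assert len(set(sel.final_labels.values())) == 4

    def test_equal_local_maxima_tie_break_to_smaller_k(self):
        ks = [2, 3, 4, 5, 6]
        grid = self.composite_grid([0.0, 0.9, 0.1, 0.9, 0.0], ks)
        vectors = two_group_vectors(n_per_group=5, jitter=0.02)
        assert select_k(grid, fake_labelings(vectors, ks), vectors).chosen_k == 3

    def test_boundary_peak_qualifies(self):
        ks = [2, 3, 4]
        grid = self.composite_grid([0.9, 0.5, 0.1], ks)
        vectors = two_group_vectors(n_per_group=3, jitter=0.02)
        assert select_k(grid, fake_labelings(vectors, ks), vectors).chosen_k == 2

    def test_flat_composite_errors(self):
        ks = [2, 3, 4]
        grid = self.composite_grid([1.0, 1.0, 1.0], ks)
        vectors = two_group_vectors(n_per_group=3, jitter=0.02)
        with pytest.raises(ValueError, match="constant|flat"):
            select_k(grid, fake_labelings(vectors, ks), vectors)

    def test_affine_rescaling_of_a_measure_changes_nothing(self):
        """Standardization makes the composite invariant to a measure's units."""
        rng = np.random.default_rng(12)
        hists, _ = planted_histograms(20, centers=(15, 45, 75), rng=rng)
        vectors = build_vectors(hists)
        labelings = cluster_solutions(vectors, methods=["ward", "kmeans"], k_range=range(2, 7))
        grid = score_grid(labelings, vectors, measures=["silhouette", "calinski_harabasz"])
        sel = select_k(grid, labelings, vectors)
        scaled = ValidityGrid(grid.scores.copy(), grid.k_range, grid.methods, grid.measures)
        scaled.scores["calinski_harabasz"] = 10.0 * scaled.scores["calinski_harabasz"] + 7.0
        sel2 = select_k(scaled, labelings, vectors)
        assert sel.chosen_k == sel2.chosen_k
        assert sel.composite_by_k == pytest.approx(sel2.composite_by_k)

    def test_monotone_dummy_measure_never_changes_chosen_k(self):
        rng = np.random.default_rng(21)
        hists, _ = planted_histograms(24, centers=(10, 40, 70, 85), rng=rng)
        vectors = build_vectors(hists)
        labelings = cluster_solutions(vectors, k_range=range(2, 8), seed=3)
        grid = score_grid(labelings, vectors, seed=3)
        pruned, removed = remove_monotonic(grid)
        base = select_k(pruned, labelings, vectors, removed)

        with_dummy = grid.scores.copy()
        with_dummy["dummy"] = [float(k) for _, k in with_dummy.index]  # strictly monotone in k
        dummy_grid = ValidityGrid(
            with_dummy, grid.k_range, grid.methods, grid.measures + ("dummy",)
        )
        pruned2, removed2 = remove_monotonic(dummy_grid)
        assert "dummy" in removed2
        sel = select_k(pruned2, labelings, vectors, removed2)
        assert sel.chosen_k == base.chosen_k

    def test_permutation_invariance_of_labels_and_k(self):
        rng = np.random.default_rng(33)
        hists, _ = planted_histograms(20, centers=(15, 50, 80), rng=rng)
        vectors = build_vectors(hists)

        def run(v):
            labelings = cluster_solutions(v, methods=["ward"], k_range=range(2, 7))
            grid = score_grid(labelings, v, measures=["silhouette", "dunn", "davies_bouldin"])
            pruned, removed = remove_monotonic(grid)
            return select_k(pruned, labelings, v, removed)

        sel1 = run(vectors)
        shuffled = vectors.sample(frac=1.0, random_state=7)
        sel2 = run(shuffled)
        assert sel1.chosen_k == sel2.chosen_k
        order = list(vectors.index)
        a = [sel1.final_labels[d] for d in order]
        b = [sel2.final_labels[d] for d in order]
        assert adjusted_rand_score(a, b) == 1.0


class TestClusterProfiles:
    def test_singleton_cluster_equals_member_vector(self):
        hists = OnsetHistogramSet({"a": hist({0: 3, 1: 4}), "b": hist({50: 5})})
        profiles = cluster_profiles({"a": 0, "b": 1}, hists)
        assert profiles.loc[0, 0] == pytest.approx(0.6)
        assert profiles.loc[1, 50] == pytest.approx(1.0)

    def test_identical_members_equal_profile(self):
        h = hist({10: 2, 11: 2})
        hists = OnsetHistogramSet({"a": h, "b": h.copy()})
        profiles = cluster_profiles({"a": 0, "b": 0}, hists)
        np.testing.assert_allclose(
            profiles.loc[0].to_numpy(), h / np.linalg.norm(h), atol=1e-12
        )

    def test_mean_matches_hand_computation(self):
        hists = OnsetHistogramSet({"a": hist({0: 1}), "b": hist({1: 1})})
        profiles = cluster_profiles({"a": 0, "b": 0}, hists)
        assert profiles.loc[0, 0] == pytest.approx(0.5)
        assert profiles.loc[0, 1] == pytest.approx(0.5)


def test_choose_clusters_recovers_planted_count():
    rng = np.random.default_rng(2)
    hists, truth = planted_histograms(32, centers=(8, 35, 60, 83), rng=rng, n_onsets=500)
    sel = choose_clusters(hists, k_range=range(2, 9), seed=2)
    assert sel.chosen_k == 4
    vectors_order = sorted(truth)
    assert adjusted_rand_score(
        [truth[d] for d in vectors_order], [sel.final_labels[d] for d in vectors_order]
    ) == 1.0
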