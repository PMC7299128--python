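"""Fuzzy c-means fitting and projection, cluster-number selection,
major-cluster condensation and heterochronic-shift classification."""
import math

import numpy as np
import pandas as pd
import pytest

from heterochron import (
    OrthologPair,
    assign_major_clusters,
    classify_shifts,
    dmin_profile,
    estimate_fuzzifier,
    fcm_fit,
    min_centroid_distance,
    project_profiles,
    select_k,
    tf_subset_comparison,
)
from heterochron.clustering import ClusterModel, MC_EARLY, MC_LATE, MC_MID, UNASSIGNED


def profiles(array, prefix="g"):
    array = np.asarray(array, dtype=float)
    return pd.DataFrame(
        array,
        index=[f"{prefix}{i}" for i in range(len(array))],
        columns=list(range(1, array.shape[1] + 1)),
    )


class TestFuzzifier:
    def test_always_above_one(self):
        for n, d in [(10, 2), (100, 4), (10_000, 8)]:
            assert estimate_fuzzifier(n, d) > 1.0

    def test_non_increasing_in_gene_count(self):
        values = [estimate_fuzzifier(n, 4) for n in (10, 100, 1000, 10_000)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_matches_published_formula_directly(self):
        n, d = 3976, 4
        expected = (
            1
            + (1418 / n + 22.05) * d**-2
            + (12.33 / n + 0.243) * d ** (-0.0406 * math.log(n) - 0.1134)
        )
        assert estimate_fuzzifier(n, d) == pytest.approx(expected, rel=1e-12)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            estimate_fuzzifier(1, 4)
        with pytest.raises(ValueError):
            estimate_fuzzifier(100, 1)


def fcm_oracle(x, k, m, init, tol=1e-10, max_iter=2000):
    """Independently coded brute-force alternating-update FCM: explicit
    loops over points and clusters, no shared code with the package."""
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    c = np.array(init, dtype=float)
    u = np.zeros((n, k))
    for _ in range(max_iter):
        u_old = u.copy()
        for i in range(n):
            dists = [np.linalg.norm(x[i] - c[j]) for j in range(k)]
            if any(dj == 0 for dj in dists):
                for j in range(k):
                    u[i, j] = 1.0 if dists[j] == 0 else 0.0
                u[i] /= u[i].sum()
            else:
                for j in range(k):
                    u[i, j] = 1.0 / sum(
                        (dists[j] / dists[l]) ** (2.0 / (m - 1.0)) for l in range(k)
                    )
        for j in range(k):
            w = u[:, j] ** m
            c[j] = (w[:, None] * x).sum(axis=0) / w.sum()
        if np.abs(u - u_old).max() < tol:
            break
    objective = sum(
        u[i, j] ** m * np.linalg.norm(x[i] - c[j]) ** 2
        for i in range(n)
        for j in range(k)
    )
    return c, u, objective


class TestFCMFit:
    def test_k1_centroid_is_the_mean(self):
        x = profiles([[0, 1, 2, 3], [2, 3, 4, 5], [4, 5, 6, 7]])
        model = fcm_fit(x, k=1, m=2.0, seed=0)
        assert model.centroids.iloc[0].tolist() == pytest.approx(
            x.to_numpy().mean(0).tolist()
        )
        assert np.allclose(model.memberships.to_numpy(), 1.0)

    def test_two_clouds_match_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        cloud1 = rng.normal([0, 0, 0, 0], 0.05, size=(5, 4))
        cloud2 = rng.normal([3, 3, -3, 3], 0.05, size=(5, 4))
        x = profiles(np.vstack([cloud1, cloud2]))
        init = x.to_numpy()[[0, 5]]
        model = fcm_fit(x, k=2, m=2.0, seed=0, init_centroids=init)
        c_or, u_or, j_or = fcm_oracle(x.to_numpy(), 2, 2.0, init)
        assert np.abs(model.centroids.to_numpy() - c_or).max() < 1e-6
        assert np.abs(model.memberships.to_numpy() - u_or).max() < 1e-6
        assert model.objective == pytest.approx(j_or, rel=1e-6)
        # centroids sit on the cloud means with confident memberships
        assert np.abs(model.centroids.to_numpy()[0] - cloud1.mean(0)).max() < 0.05
        assert np.abs(model.centroids.to_numpy()[1] - cloud2.mean(0)).max() < 0.05
        assert model.max_memberships().min() > 0.95

    def test_objective_non_increasing_on_random_data(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            x = profiles(rng.normal(size=(30, 4)))
            model = fcm_fit(x, k=4, m=1.8, seed=trial, n_restarts=1)
            diffs = np.diff(model.objective_history)
            assert (diffs <= 1e-9).all()

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        x = profiles(rng.normal(size=(40, 4)))
        model = fcm_fit(x, k=5, m=2.2, seed=0)
        sums = model.memberships.to_numpy().sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-9

    def test_k_at_least_n_rejected(self):
        x = profiles(np.eye(4))
        with pytest.raises(ValueError):
            fcm_fit(x, k=4, m=2.0, seed=0)


class TestDminAndSelectK:
    def test_k2_equals_pairwise_centroid_distance(self):
        rng = np.random.default_rng(0)
        x = profiles(
            np.vstack(
                [rng.normal(0, 0.1, (8, 4)), rng.normal(2, 0.1, (8, 4))]
            )
        )
        model = fcm_fit(x, k=2, m=2.0, seed=1)
        d = np.linalg.norm(
            model.centroids.iloc[0] - model.centroids.iloc[1]
        )
        assert min_centroid_distance(model.centroids.to_numpy()) == pytest.approx(d)

    def test_more_clusters_than_distinct_profiles_collapses_dmin(self):
        base = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0.0]])
        x = profiles(np.repeat(base, 5, axis=0))
        prof = dmin_profile(x, [6], m=1.6, seed=0)
        assert prof[6] < 0.05

    def test_elbow_drops_after_true_archetype_count(self):
        rng = np.random.default_rng(5)
        arch = np.array([[2, -1, -1, 0], [-1, 2, 0, -1], [-1, -1, 0, 2.0]])
        x = profiles(
            np.vstack([rng.normal(a, 0.05, (20, 4)) for a in arch])
        )
        prof = dmin_profile(x, range(2, 7), m=1.8, seed=0)
        drop = (prof[3] - prof[4]) / prof[3]
        assert drop > 0.5 and prof[4] < 0.5 * prof[3]

    def test_override_wins(self):
        assert select_k({2: 1.0, 3: 0.5}, override=12) == 12

    def test_elbow_rule_on_worked_profile(self):
        assert select_k({2: 1.0, 3: 0.9, 4: 0.2, 5: 0.19}) == 4

    def test_flat_profile_returns_k_min(self):
        assert select_k({4: 1.0, 5: 1.0, 6: 1.0}) == 4

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            select_k({})


def toy_model(centroids, m=2.0):
    c = np.asarray(centroids, dtype=float)
    return ClusterModel(
        k=len(c), fuzzifier_m=m,
        centroids=pd.DataFrame(c, columns=list(range(1, c.shape[1] + 1))),
        memberships=pd.DataFrame(columns=range(len(c))),
        objective=0.0,
    )


class TestProjection:
    def test_profile_on_centroid_gets_full_membership(self):
        model = toy_model([[1, 0, 0, 0], [0, 0, 0, 1]])
        mem, hard, maxmem = project_profiles(
            model, profiles([[0, 0, 0, 1]])
        )
        assert mem.iloc[0].tolist() == pytest.approx([0.0, 1.0])
        assert hard.iloc[0] == 1 and maxmem.iloc[0] == pytest.approx(1.0)

    def test_equidistant_profile_gets_uniform_memberships(self):
        model = toy_model([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]])
        mem, _, _ = project_profiles(model, profiles([[0, 0, 0, 0]]))
        assert mem.iloc[0].tolist() == pytest.approx([1 / 3] * 3)

    def test_membership_formula_by_hand(self):
        model = toy_model([[0, 0, 0, 0], [2, 0, 0, 0]], m=2.0)
        pts = profiles([[0.5, 0, 0, 0], [1.5, 0, 0, 0], [0, 1, 0, 0]])
        mem, hard, _ = project_profiles(model, pts)
        # u_1 = 1 / (1 + (d1/d2)^2) for m=2
        for i, (d1, d2) in enumerate([(0.5, 1.5), (1.5, 0.5),
                                      (1.0, np.sqrt(5))]):
            expected = 1 / (1 + (d1 / d2) ** 2)
            assert mem.iloc[i, 0] == pytest.approx(expected, abs=1e-12)
        assert hard.tolist() == [0, 1, 0]

    def test_projection_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        model = toy_model(rng.normal(size=(5, 4)), m=1.7)
        mem, _, _ = project_profiles(model, profiles(rng.normal(size=(50, 4))))
        assert np.abs(mem.sum(axis=1) - 1.0).max() < 1e-9

    def test_stage_mismatch_rejected(self):
        model = toy_model([[1, 0, 0, 0], [0, 1, 0, 0]])
        with pytest.raises(ValueError):
            project_profiles(model, profiles([[1, 0, 0]]))

    def test_self_projection_reproduces_confident_assignments(self):
        rng = np.random.default_rng(6)
        arch = np.array([[2, -1, -1, 0], [-1, 2, 0, -1], [-1, -1, 0, 2.0]])
        x = profiles(np.vstack([rng.normal(a, 0.3, (25, 4)) for a in arch]))
        model = fcm_fit(x, k=3, m=1.8, seed=0)
        mem, hard, _ = project_profiles(model, x)
        confident = model.max_memberships() >= 0.6
        assert (hard[confident] == model.hard_assignments()[confident]).all()


class TestMajorClusters:
    @pytest.mark.parametrize(
        "centroid,major",
        [
            ([1.5, -0.5, -0.5, -0.5], MC_EARLY),
            ([-0.5, 1.5, -0.5, -0.5], MC_MID),
            ([-0.5, -0.5, 1.5, -0.5], MC_MID),
            ([-0.5, -0.5, -0.5, 1.5], MC_LATE),
        ],
    )
    def test_peak_stage_maps_to_major(self, centroid, major):
        assert assign_major_clusters(toy_model([centroid]))[0] == major

    def test_u_shaped_centroid_unassigned(self):
        # high at stages 1 and 4 with near-equal peaks: ambiguous timing
        mapping = assign_major_clusters(toy_model([[1.0, -1.0, -1.0, 0.95]]))
        assert mapping[0] == UNASSIGNED

    def test_clearly_dominated_secondary_peak_is_assigned(self):
        mapping = assign_major_clusters(toy_model([[1.0, -1.0, -1.0, 0.3]]))
        assert mapping[0] == MC_EARLY

    def test_every_minor_cluster_mapped_once(self):
        rng = np.random.default_rng(1)
        model = toy_model(rng.normal(size=(12, 4)))
        mapping = assign_major_clusters(model)
        assert sorted(mapping) == list(range(12))


def series(values, genes):
    return pd.Series(values, index=genes)


class TestShiftClassification:
    MAJOR = {0: MC_EARLY, 1: MC_MID, 2: MC_LATE, 3: UNASSIGNED}

    def classify(self, minors_a, minors_b, mem_a=None, mem_b=None, **kw):
        genes_a = [f"a{i}" for i in range(len(minors_a))]
        genes_b = [f"b{i}" for i in range(len(minors_b))]
        pairs = [OrthologPair(a, b) for a, b in zip(genes_a, genes_b)]
        mem_a = mem_a or [0.9] * len(genes_a)
        mem_b = mem_b or [0.9] * len(genes_b)
        return classify_shifts(
            series(minors_a, genes_a), series(mem_a, genes_a),
            series(minors_b, genes_b), series(mem_b, genes_b),
            self.MAJOR, pairs, **kw,
        )

    def test_same_major_is_conserved(self):
        table, _ = self.classify([1], [1])
        assert table["call"].tolist() == ["conserved"]

    def test_different_major_is_heterochronic(self):
        table, _ = self.classify([0], [2])
        assert table["call"].tolist() == ["heterochronic"]

    def test_unassigned_minor_or_weak_membership_excluded(self):
        table, _ = self.classify([3, 0], [1, 2], mem_b=[0.9, 0.2])
        assert table["call"].tolist() == ["excluded", "excluded"]

    def test_summary_percentages_over_assigned_pairs(self):
        _, summary = self.classify([0, 0, 1, 3], [0, 2, 1, 1])
        assert summary["n_conserved"] == 2
        assert summary["n_heterochronic"] == 1
        assert summary["n_excluded"] == 1
        assert summary["pct_heterochronic"] == pytest.approx(100 / 3)


class TestTFContrast:
    def make_table(self, tf_split, other_split):
        rows = []
        for i in range(tf_split[0]):
            rows.append({"gene_a": f"tf{i}", "gene_b": f"x{i}", "call": "conserved"})
        for i in range(tf_split[1]):
            rows.append({"gene_a": f"tf{100+i}", "gene_b": f"y{i}",
                         "call": "heterochronic"})
        for i in range(other_split[0]):
            rows.append({"gene_a": f"o{i}", "gene_b": f"p{i}", "call": "conserved"})
        for i in range(other_split[1]):
            rows.append({"gene_a": f"q{i}", "gene_b": f"r{i}",
                         "call": "heterochronic"})
        tf_list = [f"tf{i}" for i in range(200)]
        return pd.DataFrame(rows), tf_list

    def test_proportional_table_gives_zero(self):
        table, tfs = self.make_table((50, 50), (60, 60))
        assert tf_subset_comparison(table, tfs).chi2 == pytest.approx(0.0)

    def test_matches_pearson_oracle(self):
        from test_homology import pearson_chi2_oracle

        table, tfs = self.make_table((30, 10), (25, 35))
        res = tf_subset_comparison(table, tfs)
        assert res.chi2 == pytest.approx(
            pearson_chi2_oracle([[30, 10], [25, 35]])
        )

    def test_empty_intersection_rejected(self):
        table, _ = self.make_table((5, 5), (5, 5))
        with pytest.raises(ValueError):
            tf_subset_comparison(table, ["nope"])
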