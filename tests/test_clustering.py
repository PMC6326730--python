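"""Correlation-distance k-means, paradigm labeling, distance markers."""

import itertools

import numpy as np
import pytest

from dfcengage.clustering import (clustering_accuracy, correlation_distance,
                                  distances_to_centroids, kmeans_corr,
                                  label_clusters, standardize_rows)
from dfcengage.dfc import DFCStack, n_links
from dfcengage.paradigm import Window


def brute_force_inertia(vectors, assignment):
    """Exact inertia of a partition: centroid = normalized mean of
    standardized members (the minimizer for correlation distance)."""
    xs = standardize_rows(vectors)
    total = 0.0
    for c in set(assignment):
        members = xs[[i for i, a in enumerate(assignment) if a == c]]
        centroid = members.mean(axis=0)
        centroid /= np.linalg.norm(centroid)
        total += float(np.sum(1.0 - members @ centroid))
    return total


def planted_vectors(rng, k=4, per_state=8, links=40, noise=0.05):
    bases = rng.standard_normal((k, links))
    labels = np.repeat(np.arange(k), per_state)
    x = bases[labels] + noise * rng.standard_normal((k * per_state, links))
    return x, labels


class TestKmeansCorr:
    def test_matches_exhaustive_search_k2(self, rng):
        vectors = rng.standard_normal((6, 4))
        best = min(
            brute_force_inertia(vectors, assign)
            for assign in itertools.product([0, 1], repeat=6)
            if len(set(assign)) == 2
        )
        model = kmeans_corr(vectors, k=2, n_init=50, seed=0)
        assert model.inertia == pytest.approx(best, abs=1e-9)

    def test_planted_states_recovered(self, rng):
        x, labels = planted_vectors(rng)
        model = kmeans_corr(x, k=4, n_init=20, seed=1)
        # agreement up to relabeling via the optimal bijection
        model = label_clusters(model, [str(l) for l in labels])
        assert clustering_accuracy(model, [str(l) for l in labels]) == 1.0

    def test_k1_degenerate(self, rng):
        vectors = rng.standard_normal((10, 6))
        model = kmeans_corr(vectors, k=1, n_init=5, seed=0)
        xs = standardize_rows(vectors)
        centroid = xs.mean(axis=0)
        centroid /= np.linalg.norm(centroid)
        assert np.allclose(model.centroids[0], centroid, atol=1e-10)
        assert model.inertia == pytest.approx(float(np.sum(1 - xs @ centroid)))

    def test_deterministic_per_seed(self, rng):
        x, _ = planted_vectors(rng, noise=0.5)
        a = kmeans_corr(x, k=4, n_init=10, seed=42)
        b = kmeans_corr(x, k=4, n_init=10, seed=42)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.inertia == b.inertia

    def test_fewer_distinct_vectors_than_k_raises(self):
        x = np.tile(np.random.default_rng(0).standard_normal(5), (6, 1))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_corr(x, k=2, n_init=2, seed=0)

    def test_accuracy_rises_with_separation(self, rng):
        # 3-point noise grid, 10 seeds each: mean accuracy must be monotone
        mean_acc = []
        for noise in (8.0, 3.5, 1.5):
            accs = []
            for seed in range(10):
                r = np.random.default_rng(seed)
                x, labels = planted_vectors(r, noise=noise)
                m = kmeans_corr(x, k=4, n_init=10, seed=seed)
                m = label_clusters(m, [str(l) for l in labels])
                accs.append(clustering_accuracy(m, [str(l) for l in labels]))
            mean_acc.append(np.mean(accs))
        assert mean_acc[0] < mean_acc[1] < mean_acc[2]


class TestLabelClusters:
    def _model_with_assignments(self, assignments, k=4):
        rng = np.random.default_rng(0)
        from dfcengage.clustering import StateModel
        return StateModel(centroids=standardize_rows(rng.standard_normal((k, 8))),
                          assignments=np.asarray(assignments), inertia=0.0,
                          seed=0, n_init=1, max_iter=1)

    @staticmethod
    def _brute_force_mapping(conf, tasks):
        best, best_score = None, -1
        for perm in itertools.permutations(range(len(tasks))):
            score = sum(conf[c, perm[c]] for c in range(len(tasks)))
            if score > best_score:
                best, best_score = perm, score
        return {c: tasks[best[c]] for c in range(len(tasks))}, best_score

    def test_diag_dominant_identity(self):
        tasks = ["a", "b", "c", "d"]
        window_tasks = [tasks[i] for i in range(4) for _ in range(5)]
        model = self._model_with_assignments([i for i in range(4)
                                              for _ in range(5)])
        labeled = label_clusters(model, window_tasks)
        assert labeled.cluster_tasks == {0: "a", 1: "b", 2: "c", 3: "d"}

    def test_off_diagonal_optimum_matches_enumeration(self):
        # confusion matrix whose best bijection is NOT the diagonal
        conf = np.array([[5, 9, 1, 0],
                         [8, 2, 1, 1],
                         [0, 1, 2, 9],
                         [1, 0, 8, 3]])
        tasks = ["a", "b", "c", "d"]
        window_tasks, assignments = [], []
        for c in range(4):
            for t in range(4):
                window_tasks += [tasks[t]] * conf[c, t]
                assignments += [c] * conf[c, t]
        model = self._model_with_assignments(assignments)
        labeled = label_clusters(model, window_tasks)
        expected, score = self._brute_force_mapping(conf, tasks)
        got_score = sum(conf[c, tasks.index(t)]
                        for c, t in labeled.cluster_tasks.items())
        assert got_score == score
        assert labeled.cluster_tasks == expected

    def test_missing_task_raises(self):
        model = self._model_with_assignments([0, 1, 2, 3])
        with pytest.raises(ValueError, match="distinct tasks"):
            label_clusters(model, ["a", "a", "b", "c"])


class TestClusteringAccuracy:
    def test_one_misassigned_of_32(self, rng):
        x, labels = planted_vectors(rng, per_state=8)
        model = kmeans_corr(x, k=4, n_init=10, seed=0)
        names = [str(l) for l in labels]
        model = label_clusters(model, names)
        wrong = names.copy()
        wrong[0] = "1" if names[0] == "0" else "0"
        assert clustering_accuracy(model, wrong) == pytest.approx(31 / 32)

    def test_random_assignment_null_distribution(self, rng):
        # optimal relabeling inflates chance above 1/k; the null stays
        # well below the planted-recovery regime
        from dfcengage.clustering import StateModel
        names = [str(t) for t in np.repeat(np.arange(4), 8)]
        accs = []
        centroids = standardize_rows(rng.standard_normal((4, 8)))
        for _ in range(1000):
            model = StateModel(centroids=centroids,
                               assignments=rng.integers(0, 4, 32),
                               inertia=0.0, seed=0, n_init=1, max_iter=1)
            model = label_clusters(model, names)
            accs.append(clustering_accuracy(model, names))
        assert 0.25 < np.mean(accs) < 0.45


class TestDistances:
    def _stack_and_model(self, rng):
        links = n_links(10)
        bases = standardize_rows(rng.standard_normal((4, links)))
        tasks = ["rest", "memory", "math", "video"]
        windows, z = [], []
        for i in range(16):
            t = i % 4
            windows.append(Window(index=i, task=tasks[t], start_tr=30 * i,
                                  end_tr=30 * (i + 1), block_index=i // 2))
            z.append(bases[t] + 0.05 * rng.standard_normal(links))
        stack = DFCStack(z=np.array(z), windows=windows, n_components=10)
        model = kmeans_corr(stack.z, k=4, n_init=10, seed=0)
        model = label_clusters(model, stack.tasks)
        return stack, model

    def test_rest_windows_excluded(self, rng):
        stack, model = self._stack_and_model(rng)
        table = distances_to_centroids(stack, model)
        assert set(table["task"]) == {"memory", "math", "video"}
        assert len(table) == 12

    def test_distances_bounded_and_ordered(self, rng):
        stack, model = self._stack_and_model(rng)
        table = distances_to_centroids(stack, model)
        assert ((table["dist_he"] >= 0) & (table["dist_he"] <= 2)).all()
        # windows sit near their own (HE) centroid, far from rest
        assert (table["dist_he"] < table["dist_le"]).all()

    def test_vector_equal_to_centroid(self, rng):
        stack, model = self._stack_and_model(rng)
        rest_centroid = model.centroid_for_task("rest")
        mem_centroid = model.centroid_for_task("memory")
        assert correlation_distance(rest_centroid, rest_centroid) \
            == pytest.approx(0.0, abs=1e-12)
        d = correlation_distance(rest_centroid, mem_centroid)
        assert d > 0.5  # separated planted states

    def test_anticorrelated_distance_two(self):
        v = np.random.default_rng(0).standard_normal(20)
        assert correlation_distance(v, -v) == pytest.approx(2.0)
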