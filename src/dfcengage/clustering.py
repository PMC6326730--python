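"""Per-subject k-means over window connectivity vectors with correlation distance.

Correlation distance d(x, c) = 1 - Pearson(x, c) is realized by centering
each vector to zero mean and scaling to unit norm across links; on such rows
1 - x.c equals the correlation distance and the normalized cluster mean is
the exact minimizer of the within-cluster distance sum (spherical k-means).
Clusters are labeled afterwards by the optimal one-to-one assignment to the
paradigm's tasks, which yields per-task high-engagement centroids (HE-FC)
and the rest centroid as the low-engagement pattern (LE-FC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import kmeans_plusplus

from .dfc import DFCStack


def standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center each row to zero mean and scale to unit L2 norm."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant vector has undefined correlation distance")
    return x / norms


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    xs = standardize_rows(x[None, :])[0]
    ys = standardize_rows(y[None, :])[0]
    return float(1.0 - xs @ ys)


@dataclass(frozen=True)
class StateModel:
    centroids: np.ndarray                 # k x links, row-standardized
    assignments: np.ndarray               # per-window cluster id in [0, k)
    inertia: float                        # sum of correlation distances
    seed: int
    n_init: int
    max_iter: int
    cluster_tasks: dict[int, str] | None = None   # cluster id -> task label

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def centroid_for_task(self, task: str) -> np.ndarray:
        if self.cluster_tasks is None:
            raise ValueError("clusters are not labeled yet")
        for cid, t in self.cluster_tasks.items():
            if t == task:
                return self.centroids[cid]
        raise KeyError(task)


def _lloyd(xs: np.ndarray, k: int, max_iter: int, rng: np.random.Generator) -> tuple:
    n = xs.shape[0]
    centers, _ = kmeans_plusplus(
        xs, n_clusters=k, random_state=int(rng.integers(2**31)))
    centers = standardize_rows(centers)
    assign = np.full(n, -1)
    inertia = np.inf
    reseeded = False
    for _ in range(max_iter):
        sim = xs @ centers.T                      # Pearson r to each centroid
        new_assign = np.argmax(sim, axis=1)
        new_inertia = float(np.sum(1.0 - sim[np.arange(n), new_assign]))
        # spherical Lloyd descends (except across an empty-cluster re-seed)
        assert reseeded or new_inertia <= inertia + 1e-9, "inertia increased"
        if np.array_equal(new_assign, assign):
            inertia = new_inertia
            break
        assign, inertia = new_assign, new_inertia
        reseeded = False
        for c in range(k):
            members = xs[assign == c]
            if len(members) == 0:                 # re-seed at the farthest point
                far = int(np.argmin(sim[np.arange(n), assign]))
                centers[c] = xs[far]
                assign[far] = c
                reseeded = True
            else:
                centers[c] = members.mean(axis=0)
        centers = standardize_rows(centers)
    return centers, assign, inertia


def kmeans_corr(
    vectors: np.ndarray,
    k: int = 4,
    max_iter: int = 1000,
    n_init: int = 100,
    seed: int = 0,
) -> StateModel:
    """K-means with correlation distance, k-means++ seeding, best of n_init runs.

    Deterministic per seed.  Raises if there are fewer distinct vectors than k.
    """
    xs = standardize_rows(np.asarray(vectors, dtype=float))
    if xs.shape[0] < k:
        raise ValueError("need at least k window vectors")
    if np.unique(np.round(xs, 12), axis=0).shape[0] < k:
        raise ValueError("fewer distinct vectors than clusters")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers, assign, inertia = _lloyd(xs, k, max_iter, rng)
        if best is None or inertia < best[2]:
            best = (centers, assign, inertia)
    centers, assign, inertia = best
    return StateModel(centroids=centers, assignments=assign, inertia=inertia,
                      seed=seed, n_init=n_init, max_iter=max_iter)


def label_clusters(model: StateModel, window_tasks: list[str]) -> StateModel:
    """Assign each cluster a task by the agreement-maximizing bijection.

    Searches all one-to-one cluster-to-task mappings (Hungarian assignment on
    the confusion matrix); ties resolve toward the lexicographically smallest
    task for the lowest cluster id.
    """
    tasks = sorted(set(window_tasks))
    if len(tasks) != model.k:
        raise ValueError(f"k={model.k} but {len(tasks)} distinct tasks in windows")
    conf = np.zeros((model.k, len(tasks)))
    t_index = {t: j for j, t in enumerate(tasks)}
    for cid, task in zip(model.assignments, window_tasks):
        conf[cid, t_index[task]] += 1
    row, col = linear_sum_assignment(-conf)
    mapping = {int(c): tasks[j] for c, j in zip(row, col)}
    return StateModel(
        centroids=model.centroids, assignments=model.assignments,
        inertia=model.inertia, seed=model.seed, n_init=model.n_init,
        max_iter=model.max_iter, cluster_tasks=mapping,
    )


def clustering_accuracy(model: StateModel, window_tasks: list[str]) -> float:
    """Fraction of windows whose mapped cluster task equals the ground truth."""
    if model.cluster_tasks is None:
        raise ValueError("label clusters first")
    hits = sum(model.cluster_tasks[int(c)] == t
               for c, t in zip(model.assignments, window_tasks))
    return hits / len(window_tasks)


def distances_to_centroids(
    stack: DFCStack,
    model: StateModel,
    rest_task: str = "rest",
) -> pd.DataFrame:
    """Correlation distance of each task window to its HE and the LE centroid.

    dist_HE = 1 - r(window, centroid labeled with the window's task);
    dist_LE = 1 - r(window, rest-labeled centroid).  Rest windows are
    excluded (they have no HE pattern distinct from LE).
    """
    if model.cluster_tasks is None:
        raise ValueError("label clusters first")
    xs = standardize_rows(stack.z)
    le = model.centroid_for_task(rest_task)
    rows = []
    for i, w in enumerate(stack.windows):
        if w.task == rest_task:
            continue
        he = model.centroid_for_task(w.task)
        rows.append({
            "window": w.index,
            "task": w.task,
            "dist_he": float(1.0 - xs[i] @ he),
            "dist_le": float(1.0 - xs[i] @ le),
        })
    return pd.DataFrame(rows)
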