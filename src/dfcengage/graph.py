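"""Window-wise community structure and participation coefficients.

Each window's connectivity matrix is treated as a weighted graph (negative
weights zeroed: the participation coefficient is defined on positive
connection strength).  Community structure is estimated with the Louvain
modularity algorithm, stabilized by consensus clustering: Louvain is
repeated n_reps times, the node-by-node co-assignment (agreement) matrix is
thresholded and re-clustered until it is block-constant.  The participation
coefficient of node i,

    B_i = 1 - sum_s (kappa_is / kappa_i)^2,

measures how evenly i's positive strength kappa_i spreads over the modules s
(0: all links within its own module; toward 1: uniform across modules).  Its
node average B_T indexes the brainwide integration level of window T.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .dfc import DFCStack

logger = logging.getLogger(__name__)


def _positive_part(adjacency: np.ndarray) -> np.ndarray:
    adjacency = np.asarray(adjacency, dtype=float)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adjacency, adjacency.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    pos = np.where(adjacency > 0, adjacency, 0.0)
    pos = (pos + pos.T) / 2.0   # remove float-level asymmetry for igraph
    np.fill_diagonal(pos, 0.0)
    return pos


def modularity(adjacency: np.ndarray, membership: np.ndarray, gamma: float = 1.0) -> float:
    """Newman-Girvan modularity of a partition on the positive graph."""
    W = _positive_part(adjacency)
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    k = W.sum(axis=1)
    membership = np.asarray(membership)
    same = membership[:, None] == membership[None, :]
    return float(((W - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)


@dataclass(frozen=True)
class Partition:
    membership: np.ndarray      # contiguous module ids from 0
    q: float                    # modularity on the source graph

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.size and sorted(set(m.tolist())) != list(range(m.max() + 1)):
            raise ValueError("module ids must be contiguous from 0")

    @property
    def n_modules(self) -> int:
        return int(self.membership.max()) + 1 if self.membership.size else 0


def _relabel(membership: list[int]) -> np.ndarray:
    seen: dict[int, int] = {}
    out = []
    for m in membership:
        if m not in seen:
            seen[m] = len(seen)
        out.append(seen[m])
    return np.asarray(out)


def louvain(adjacency: np.ndarray, gamma: float = 1.0, seed: int = 0) -> Partition:
    """One Louvain run on the positive part of the graph (seeded, stochastic).

    An all-zero positive graph returns the single-module partition with Q = 0.
    """
    W = _positive_part(adjacency)
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if W.sum() == 0:
        return Partition(membership=np.zeros(n, dtype=int), q=0.0)
    g = ig.Graph.Weighted_Adjacency(W.tolist(), mode="undirected", attr="weight")
    random.seed(seed)   # python-igraph draws node orders from Python's RNG
    part = g.community_multilevel(weights="weight", resolution=gamma)
    membership = _relabel(part.membership)
    return Partition(membership=membership, q=modularity(W, membership, gamma))


def agreement_matrix(adjacency: np.ndarray, n_reps: int, gamma: float,
                     seed: int) -> tuple[np.ndarray, list[Partition]]:
    n = adjacency.shape[0]
    agree = np.zeros((n, n))
    parts = []
    for r in range(n_reps):
        p = louvain(adjacency, gamma=gamma, seed=seed + r)
        parts.append(p)
        agree += p.membership[:, None] == p.membership[None, :]
    agree /= n_reps
    np.fill_diagonal(agree, 1.0)
    return agree, parts


def consensus_partition(
    adjacency: np.ndarray,
    n_reps: int = 500,
    tau: float = 0.5,
    gamma: float = 1.0,
    seed: int = 0,
    max_outer: int = 50,
) -> Partition:
    """Lancichinetti-Fortunato consensus over repeated Louvain runs.

    Build the agreement matrix over n_reps Louvain runs, zero entries below
    tau, and re-cluster the agreement graph, iterating until all runs agree
    (the agreement matrix is block-constant 0/1).  Modularity is reported on
    the original graph.  Deterministic per seed.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not (0 < tau < 1):
        raise ValueError("tau must be in (0, 1)")
    current = np.asarray(adjacency, dtype=float)
    best = None
    for outer in range(max_outer):
        agree, parts = agreement_matrix(current, n_reps, gamma,
                                        seed + 10_000 * outer)
        binary = np.isclose(agree, 0) | np.isclose(agree, 1)
        if binary.all():
            membership = parts[0].membership
            return Partition(membership=membership,
                             q=modularity(adjacency, membership, gamma))
        thresholded = np.where(agree >= tau, agree, 0.0)
        np.fill_diagonal(thresholded, 0.0)
        best = parts[0]
        current = thresholded
    logger.warning("consensus did not converge in %d outer iterations", max_outer)
    return Partition(membership=best.membership,
                     q=modularity(adjacency, best.membership, gamma))


def participation(adjacency: np.ndarray, partition: Partition) -> pd.DataFrame:
    """Per-node participation coefficient on positive weights.

    Returns a DataFrame with columns node, strength, b (participation).
    Nodes with zero positive strength get b = 0 by convention.
    """
    W = _positive_part(adjacency)
    n = W.shape[0]
    membership = np.asarray(partition.membership)
    if membership.shape != (n,):
        raise ValueError("partition must cover all nodes")
    kappa = W.sum(axis=1)
    # per-node strength into each module: n x N
    one_hot = np.zeros((n, partition.n_modules))
    one_hot[np.arange(n), membership] = 1.0
    kappa_s = W @ one_hot
    with np.errstate(invalid="ignore", divide="ignore"):
        b = 1.0 - np.sum((kappa_s / kappa[:, None]) ** 2, axis=1)
    isolated = kappa == 0
    if isolated.any():
        logger.warning("%d nodes have zero positive strength; B set to 0",
                       int(isolated.sum()))
        b[isolated] = 0.0
    return pd.DataFrame({"node": np.arange(n), "strength": kappa, "b": b})


def windowed_participation(
    stack: DFCStack,
    n_reps: int = 500,
    tau: float = 0.5,
    gamma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Consensus community structure and mean participation per window.

    Graphs are built from the Fisher-z window matrices (monotone in r, so
    module structure is unchanged; strengths differ only by the transform's
    scaling).  The window index is mixed into the Louvain seed so the
    repetitions differ per window while the whole run stays reproducible.
    Returns columns window, task, b_t, n_modules, q.
    """
    rows = []
    for i, w in enumerate(stack.windows):
        mat = stack.matrix(i)
        part = consensus_partition(mat, n_reps=n_reps, tau=tau, gamma=gamma,
                                   seed=seed + 1_000_003 * w.index)
        b = participation(mat, part)
        rows.append({"window": w.index, "task": w.task,
                     "b_t": float(b["b"].mean()),
                     "n_modules": part.n_modules, "q": part.q})
    return pd.DataFrame(rows)
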