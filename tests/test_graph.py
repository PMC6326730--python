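"""Louvain communities, consensus clustering, participation coefficients."""

import itertools

import numpy as np
import pytest

from dfcengage.dfc import DFCStack, vectorize
from dfcengage.graph import (Partition, consensus_partition, louvain,
                             modularity, participation,
                             windowed_participation)
from dfcengage.paradigm import Window


def all_partitions(n):
    """Every set partition of range(n) as a membership vector (Bell(n) many)."""
    if n == 1:
        yield [0]
        return
    for rest in all_partitions(n - 1):
        k = max(rest) + 1
        for c in range(k + 1):
            yield rest + [c]


def two_cliques(weak=0.1):
    a = np.zeros((8, 8))
    for i, j in itertools.combinations(range(4), 2):
        a[i, j] = a[j, i] = 1.0
        a[i + 4, j + 4] = a[j + 4, i + 4] = 1.0
    a[3, 4] = a[4, 3] = weak
    return a


class TestLouvain:
    def test_two_cliques_split(self):
        part = louvain(two_cliques(), seed=0)
        assert part.n_modules == 2
        assert len(set(part.membership[:4])) == 1
        assert len(set(part.membership[4:])) == 1

    def test_matches_brute_force_modularity(self):
        # sparse random weighted graph: enough structure for modularity to be
        # meaningfully positive (a dense uniform graph has q_max ~ 0)
        g = np.random.default_rng(0)
        w = g.random((8, 8)) * (g.random((8, 8)) < 0.4)
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        q_max = max(modularity(w, np.asarray(m)) for m in all_partitions(8))
        for seed in range(20):
            q = louvain(w, seed=seed).q
            assert q <= q_max + 1e-12
            assert q >= 0.95 * q_max

    def test_complete_equal_graph_trivial(self):
        w = np.ones((6, 6))
        np.fill_diagonal(w, 0.0)
        assert modularity(w, np.zeros(6, dtype=int)) == pytest.approx(0.0)
        assert louvain(w, seed=0).q <= 1e-9

    def test_all_zero_graph_single_module(self):
        part = louvain(np.zeros((5, 5)), seed=0)
        assert part.n_modules == 1 and part.q == 0.0

    def test_negative_weights_zeroed(self):
        w = two_cliques()
        w[0, 7] = w[7, 0] = -5.0  # must not bridge the cliques
        assert louvain(w, seed=0).n_modules == 2

    def test_q_at_least_single_module(self, rng):
        w = rng.random((10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        for seed in range(5):
            assert louvain(w, seed=seed).q >= modularity(w, np.zeros(10, int))


class TestConsensus:
    def test_unambiguous_graph_converges_immediately(self):
        part = consensus_partition(two_cliques(weak=0.01), n_reps=20, seed=0)
        assert part.n_modules == 2

    def test_planted_two_block_recovered(self, rng):
        n = 12
        m = np.array([0] * 6 + [1] * 6)
        w = np.where(m[:, None] == m[None, :], 0.9, 0.05) \
            + 0.02 * rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        part = consensus_partition(w, n_reps=50, seed=1)
        assert part.n_modules == 2
        assert len(set(part.membership[:6])) == 1
        assert len(set(part.membership[6:])) == 1

    def test_n_reps_two_terminates(self, rng):
        w = rng.random((10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        part = consensus_partition(w, n_reps=2, seed=0)
        assert part.membership.shape == (10,)

    def test_deterministic_per_seed(self, rng):
        w = rng.random((12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        a = consensus_partition(w, n_reps=20, seed=5)
        b = consensus_partition(w, n_reps=20, seed=5)
        assert np.array_equal(a.membership, b.membership)

    def test_bad_parameters_raise(self):
        with pytest.raises(ValueError):
            consensus_partition(two_cliques(), n_reps=1)
        with pytest.raises(ValueError):
            consensus_partition(two_cliques(), tau=1.5)


def participation_oracle(w, membership):
    """Naive per-node summation of Eq-style strength ratios."""
    n = w.shape[0]
    pos = np.where(w > 0, w, 0.0)
    np.fill_diagonal(pos, 0.0)
    out = np.zeros(n)
    for i in range(n):
        kappa = sum(pos[i, j] for j in range(n))
        if kappa == 0:
            continue
        acc = 0.0
        for s in set(membership):
            k_s = sum(pos[i, j] for j in range(n) if membership[j] == s)
            acc += (k_s / kappa) ** 2
        out[i] = 1.0 - acc
    return out


class TestParticipation:
    def test_all_links_within_module_zero(self):
        part = Partition(membership=np.array([0, 0, 0, 0, 1, 1, 1, 1]), q=0.5)
        b = participation(two_cliques(weak=0.0), part)
        assert np.allclose(b["b"], 0.0)

    def test_equal_strength_to_four_modules(self):
        # hub node 0 with equal weight to one node in each of 4 modules
        w = np.zeros((9, 9))
        membership = np.array([0, 0, 0, 1, 1, 2, 2, 3, 3])
        for j, s in [(1, 0), (3, 1), (5, 2), (7, 3)]:
            w[0, j] = w[j, 0] = 1.0
        part = Partition(membership=membership, q=0.0)
        b = participation(w, part)
        assert b.loc[0, "b"] == pytest.approx(1 - 4 * (1 / 4) ** 2)

    def test_matches_naive_oracle(self, rng):
        w = rng.standard_normal((10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        membership = rng.integers(0, 3, 10)
        part = Partition(membership=np.asarray(
            np.unique(membership, return_inverse=True)[1]), q=0.0)
        b = participation(w, part)
        assert np.allclose(b["b"], participation_oracle(w, part.membership))

    def test_scale_invariance(self, rng):
        w = np.abs(rng.standard_normal((8, 8)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        part = louvain(w, seed=0)
        a = participation(w, part)["b"]
        b = participation(17.3 * w, part)["b"]
        assert np.allclose(a, b)

    def test_upper_bound(self, rng):
        w = np.abs(rng.standard_normal((12, 12)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        part = Partition(membership=rng.permutation(np.repeat(np.arange(3), 4)),
                         q=0.0)
        b = participation(w, part)
        assert (b["b"] <= 1 - 1 / 3 + 1e-12).all()
        assert (b["b"] >= 0).all()

    def test_isolated_node_zero_with_warning(self, caplog):
        w = two_cliques(weak=0.0)
        w[0, :] = w[:, 0] = -1.0  # only negative links -> zero positive strength
        np.fill_diagonal(w, 0.0)
        part = Partition(membership=np.array([0, 0, 0, 0, 1, 1, 1, 1]), q=0.0)
        with caplog.at_level("WARNING"):
            b = participation(w, part)
        assert b.loc[0, "b"] == 0.0
        assert "zero positive strength" in caplog.text


def _stack_from_matrices(mats, tasks):
    z = np.array([vectorize(m) for m in mats])
    windows = [Window(index=i, task=t, start_tr=30 * i, end_tr=30 * (i + 1),
                      block_index=i) for i, t in enumerate(tasks)]
    return DFCStack(z=z, windows=windows, n_components=mats[0].shape[0])


class TestWindowedParticipation:
    def test_identical_windows_equal_bt(self):
        m = np.repeat(np.arange(2), 5)
        w = np.where(m[:, None] == m[None, :], 0.8, 0.1).astype(float)
        np.fill_diagonal(w, 0.0)
        stack = _stack_from_matrices([w] * 4, ["memory"] * 4)
        out = windowed_participation(stack, n_reps=16, seed=0)
        # per-window seeds differ, but a clear-cut graph yields one answer
        assert out["b_t"].nunique() == 1

    def test_block_vs_uniform_ordering(self):
        # under the planted two-module partition, a block-diagonal graph is
        # fully segregated (B ~ 0) and a uniform graph maximally distributed
        m = np.repeat(np.arange(2), 5)
        part = Partition(membership=m, q=0.0)
        block = np.where(m[:, None] == m[None, :], 0.8, 0.01).astype(float)
        np.fill_diagonal(block, 0.0)
        uniform = np.full((10, 10), 0.5)
        np.fill_diagonal(uniform, 0.0)
        b_block = participation(block, part)["b"].mean()
        b_uniform = participation(uniform, part)["b"].mean()
        assert b_block < b_uniform

    def test_between_weight_grid_raises_bt(self):
        m = np.repeat(np.arange(2), 5)
        bts = []
        for between in (0.05, 0.2, 0.4):
            w = np.where(m[:, None] == m[None, :], 0.8, between).astype(float)
            np.fill_diagonal(w, 0.0)
            part = Partition(membership=m, q=0.0)
            bts.append(participation(w, part)["b"].mean())
        assert bts[0] < bts[1] < bts[2]

    def test_synthetic_subject_end_to_end(self, small_subject, paradigm):
        from dfcengage.dfc import windowed_connectivity
        from dfcengage.paradigm import segment_windows
        stack = windowed_connectivity(small_subject.timeseries,
                                      segment_windows(paradigm))
        out = windowed_participation(stack, n_reps=16, seed=3)
        assert len(out) == 32
        assert ((out["b_t"] >= 0) & (out["b_t"] <= 1)).all()
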