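"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own code paths: modularity
and the spin-glass energy are recomputed by naive pair sums, optimal
partitions by exhaustive enumeration of set partitions (feasible to n=8),
and agreement indices by direct pair counting.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from cranionet import AnatomicalNetwork, Partition, builtin_head_network


# ---------------------------------------------------------------------------
# small named graphs
# ---------------------------------------------------------------------------

def _net(n: int, edges: list[tuple[int, int]]) -> AnatomicalNetwork:
    return AnatomicalNetwork.from_edges([f"n{i}" for i in range(1, n + 1)], edges)


@pytest.fixture(scope="session")
def two_triangles() -> AnatomicalNetwork:
    return _net(6, [(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])


@pytest.fixture(scope="session")
def k5() -> AnatomicalNetwork:
    return _net(5, [(i, j) for i in range(1, 6) for j in range(i + 1, 6)])


@pytest.fixture(scope="session")
def two_cliques_bridge() -> AnatomicalNetwork:
    """K4 + K4 joined by a single bridge edge."""
    edges = [(i, j) for i in range(1, 5) for j in range(i + 1, 5)]
    edges += [(i, j) for i in range(5, 9) for j in range(i + 1, 9)]
    edges.append((4, 5))
    return _net(8, edges)


@pytest.fixture(scope="session")
def head():
    """(network, symmetry) of the packaged 39-node head model."""
    return builtin_head_network()


def random_network(n: int, p: float, seed: int) -> AnatomicalNetwork:
    """Erdos-Renyi graph, resampled until it has at least one edge."""
    rng = np.random.default_rng(seed)
    while True:
        A = np.triu((rng.random((n, n)) < p).astype(np.int8), k=1)
        A = A + A.T
        if A.sum() > 0:
            return AnatomicalNetwork(
                [__import__("cranionet").NodeRecord(i + 1, f"n{i + 1}") for i in range(n)],
                A,
            )


def random_partition(n: int, k: int, seed: int) -> Partition:
    rng = np.random.default_rng(seed)
    return Partition.from_labels(rng.integers(1, k + 1, size=n))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def set_partitions(n: int):
    """All set partitions of range(n) as label tuples (restricted growth)."""

    def rec(prefix: list[int], next_label: int):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(next_label + 1):
            yield from rec(prefix + [lab], max(next_label, lab + 1))

    yield from rec([0], 1)


def naive_modularity(network: AnatomicalNetwork, labels) -> float:
    """Q by direct double sum over ordered node pairs."""
    A = np.asarray(network.adjacency, dtype=float)
    k = network.degrees.astype(float)
    m = network.m
    labels = np.asarray(labels)
    total = 0.0
    for i in range(network.n):
        for j in range(network.n):
            if labels[i] == labels[j]:
                total += A[i, j] - k[i] * k[j] / (2 * m)
    return total / (2 * m)


def naive_hamiltonian(network: AnatomicalNetwork, labels, gamma: float = 1.0) -> float:
    """H by direct sum over unordered distinct pairs."""
    A = np.asarray(network.adjacency, dtype=float)
    k = network.degrees.astype(float)
    two_m = 2.0 * network.m
    labels = np.asarray(labels)
    H = 0.0
    for i in range(network.n):
        for j in range(i + 1, network.n):
            if labels[i] == labels[j]:
                H -= A[i, j] - gamma * k[i] * k[j] / two_m
    return H


def brute_force_best(network: AnatomicalNetwork, max_communities=None):
    """(best Q, one optimal label tuple) by exhaustive enumeration."""
    best_q, best_labels = -2.0, None
    for labels in set_partitions(network.n):
        if max_communities is not None and len(set(labels)) > max_communities:
            continue
        q = naive_modularity(network, labels)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return best_q, best_labels


def pair_counting_indices(a, b) -> tuple[float, float]:
    """(Rand index, arithmetic-mean NMI) by direct pair counting / entropy."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            if (a[i] == a[j]) == (b[i] == b[j]):
                agree += 1
    rand = agree / (n * (n - 1) / 2)

    def entropy(x):
        _, counts = np.unique(x, return_counts=True)
        p = counts / n
        return -float(np.sum(p * np.log(p)))

    h_a, h_b = entropy(a), entropy(b)
    mi = 0.0
    for ca in np.unique(a):
        for cb in np.unique(b):
            n_ab = np.sum((a == ca) & (b == cb))
            if n_ab > 0:
                n_a, n_b = np.sum(a == ca), np.sum(b == cb)
                mi += (n_ab / n) * math.log(n * n_ab / (n_a * n_b))
    denom = (h_a + h_b) / 2
    nmi = 1.0 if denom == 0 else mi / denom
    return rand, nmi
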