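"""Partition quality functions shared by all detectors.

Two equivalent views of community quality are used:

* Newman modularity ``Q = sum_c [ L_c/m - (d_c/(2m))^2 ]`` with ``L_c``
  the number of edges inside community ``c`` and ``d_c`` its total degree;
* the Potts-model spin-glass energy with a degree-preserving
  (configuration-model) null,
  ``H = - sum_{i<j} (A_ij - gamma * k_i k_j / (2m)) * delta(sigma_i, sigma_j)``,
  summed over unordered distinct node pairs.

At resolution ``gamma = 1`` the two are affinely related on a fixed graph:
``H + m*Q = -sum_i k_i^2 / (4m)`` for every partition, so minimizing H is
the same as maximizing Q.  The annealers work with H; reported scores
carry both values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .errors import DataError
from .network import AnatomicalNetwork

__all__ = [
    "Partition",
    "ModularityScore",
    "modularity",
    "hamiltonian",
    "delta_hamiltonian",
    "score_partition",
    "partition_to_json",
    "partition_from_json",
    "write_partition_json",
    "read_partition_json",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of every node id to a positive-integer community label."""

    assignment: Dict[int, int]

    def __post_init__(self) -> None:
        for i, c in self.assignment.items():
            if not (isinstance(c, (int, np.integer)) and c >= 1):
                raise DataError(f"community label of node {i} must be a positive int")
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def label_of(self, node_id: int) -> int:
        return self.assignment[node_id]

    def communities(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i in sorted(self.assignment):
            out.setdefault(self.assignment[i], []).append(i)
        return out

    def sizes(self) -> tuple[int, ...]:
        """Community sizes in ascending order."""
        return tuple(sorted(len(v) for v in self.communities().values()))

    def canonical(self) -> "Partition":
        """Relabel communities 1..k by first appearance in node-id order."""
        relabel: dict[int, int] = {}
        out: dict[int, int] = {}
        for i in sorted(self.assignment):
            c = self.assignment[i]
            if c not in relabel:
                relabel[c] = len(relabel) + 1
            out[i] = relabel[c]
        return Partition(out)

    def labels_for(self, network: AnatomicalNetwork) -> np.ndarray:
        """Label array in node order; raises if the partition misses a node."""
        _check_cover(network, self)
        return np.array([self.assignment[i] for i in range(1, network.n + 1)])

    @classmethod
    def from_labels(cls, labels: np.ndarray | list[int]) -> "Partition":
        """Build from a label array indexed in node order (0-based array)."""
        return cls({i + 1: int(c) for i, c in enumerate(labels)})


@dataclass(frozen=True)
class ModularityScore:
    """Q, the resolution gamma, and the spin-glass energy H of one partition."""

    Q: float
    gamma: float
    H: float


def _check_cover(network: AnatomicalNetwork, partition: Partition) -> None:
    want = set(range(1, network.n + 1))
    have = set(partition.assignment)
    if have != want:
        missing = sorted(want - have)[:5]
        extra = sorted(have - want)[:5]
        raise DataError(
            f"partition does not cover the network (missing {missing}, extra {extra})"
        )


def _community_stats(network: AnatomicalNetwork, labels: np.ndarray):
    """Internal edge count L_c and total degree d_c per community label."""
    A = network.adjacency
    k = network.degrees
    stats: dict[int, tuple[float, float]] = {}
    for c in np.unique(labels):
        mask = labels == c
        L_c = A[np.ix_(mask, mask)].sum() / 2.0
        stats[int(c)] = (float(L_c), float(k[mask].sum()))
    return stats


def modularity(network: AnatomicalNetwork, partition: Partition) -> float:
    """Newman modularity Q of a partition under the configuration-model null."""
    if network.m == 0:
        raise DataError("modularity is undefined for an edgeless network")
    labels = partition.labels_for(network)
    m = network.m
    return float(
        sum(L / m - (d / (2 * m)) ** 2 for L, d in _community_stats(network, labels).values())
    )


def hamiltonian(
    network: AnatomicalNetwork, partition: Partition, gamma: float = 1.0
) -> float:
    """Spin-glass energy H at resolution gamma (unordered distinct pairs)."""
    if network.m == 0:
        raise DataError("the Hamiltonian is undefined for an edgeless network")
    if gamma <= 0:
        raise DataError("gamma must be positive")
    labels = partition.labels_for(network)
    k = network.degrees
    two_m = 2.0 * network.m
    H = 0.0
    for c in np.unique(labels):
        mask = labels == c
        L_c = network.adjacency[np.ix_(mask, mask)].sum() / 2.0
        kc = k[mask]
        null_pairs = (kc.sum() ** 2 - (kc**2).sum()) / 2.0
        H -= L_c - gamma * null_pairs / two_m
    return float(H)


def delta_hamiltonian(
    network: AnatomicalNetwork,
    partition: Partition,
    node: int,
    new_label: int,
    gamma: float = 1.0,
) -> float:
    """Energy change of relabeling one node, from its adjacency row only.

    Uses the node's edge counts into the source and target communities and
    the community degree totals; O(n) instead of a full recomputation.
    """
    if not 1 <= node <= network.n:
        raise DataError(f"unknown node id {node}")
    if new_label < 1:
        raise DataError("community labels must be positive integers")
    labels = partition.labels_for(network)
    s = labels[node - 1]
    if s == new_label:
        raise DataError(f"node {node} already has label {new_label}")
    row = network.adjacency[node - 1]
    k = network.degrees
    two_m = 2.0 * network.m
    e_s = float(row[labels == s].sum())
    e_t = float(row[labels == new_label].sum())
    d_s = float(k[labels == s].sum())  # includes k_node
    d_t = float(k[labels == new_label].sum())
    k_i = float(k[node - 1])
    return -(e_t - e_s) + gamma * k_i * (d_t - d_s + k_i) / two_m


def score_partition(
    network: AnatomicalNetwork, partition: Partition, gamma: float = 1.0
) -> ModularityScore:
    return ModularityScore(
        Q=modularity(network, partition),
        gamma=gamma,
        H=hamiltonian(network, partition, gamma),
    )


# ---------------------------------------------------------------------------
# interchange format: partition JSON keyed by node name
# ---------------------------------------------------------------------------

def partition_to_json(
    partition: Partition,
    network: AnatomicalNetwork,
    Q: Optional[float] = None,
) -> dict:
    _check_cover(network, partition)
    if Q is None and network.m > 0:
        Q = modularity(network, partition)
    return {
        "labels": {
            network.name_of(i): int(c) for i, c in sorted(partition.assignment.items())
        },
        "n_communities": partition.n_communities,
        "Q": Q,
    }


def partition_from_json(obj: dict, network: AnatomicalNetwork) -> Partition:
    try:
        labels = obj["labels"]
    except (TypeError, KeyError):
        raise DataError("partition JSON must contain a 'labels' object") from None
    assignment = {network.id_of(nm): int(c) for nm, c in labels.items()}
    p = Partition(assignment)
    _check_cover(network, p)
    return p


def write_partition_json(
    partition: Partition,
    network: AnatomicalNetwork,
    path: str | Path,
    Q: Optional[float] = None,
) -> None:
    Path(path).write_text(
        json.dumps(partition_to_json(partition, network, Q=Q), indent=2, sort_keys=True)
        + "\n"
    )


def read_partition_json(path: str | Path, network: AnatomicalNetwork) -> Partition:
    try:
        obj = json.loads(Path(path).read_text())
    except FileNotFoundError:
        raise DataError(f"partition file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise DataError(f"invalid partition JSON in {path}: {exc}") from None
    return partition_from_json(obj, network)
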