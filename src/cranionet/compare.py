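"""Label-permutation-invariant partition comparison, symmetry auditing,
consensus over stochastic runs, and per-module summaries.

Two partitions are *equivalent* when one is a relabeling of the other.
Disagreements are counted under the best label matching, computed by
maximum-weight assignment on the contingency table, so the reported count
is the minimum over all label permutations.  Rand index and normalized
mutual information (arithmetic-mean normalization) quantify partial
agreement on the usual [0, 1] scales.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import scipy.optimize
from sklearn.metrics import normalized_mutual_info_score, rand_score

from .errors import DataError
from .modularity import Partition
from .network import AnatomicalNetwork, SymmetryMap
from .spinglass import DetectionResult

__all__ = [
    "PartitionComparison",
    "ConsensusResult",
    "ModuleReport",
    "compare_partitions",
    "is_symmetric_partition",
    "consensus_partition",
    "module_summary",
]


@dataclass(frozen=True)
class PartitionComparison:
    equivalent: bool
    disagreement_ids: frozenset[int]
    n_disagreements: int
    rand_index: float
    nmi: float


def _aligned_labels(p1: Partition, p2: Partition):
    ids = sorted(p1.assignment)
    if ids != sorted(p2.assignment):
        raise DataError("partitions cover different node sets")
    a = np.array([p1.assignment[i] for i in ids])
    b = np.array([p2.assignment[i] for i in ids])
    return np.array(ids), a, b


def compare_partitions(p1: Partition, p2: Partition) -> PartitionComparison:
    """Compare two partitions of the same node set, ignoring label names."""
    ids, a, b = _aligned_labels(p1, p2)
    ua, inv_a = np.unique(a, return_inverse=True)
    ub, inv_b = np.unique(b, return_inverse=True)
    contingency = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(contingency, (inv_a, inv_b), 1)
    rows, cols = scipy.optimize.linear_sum_assignment(contingency, maximize=True)
    matched = set(zip(rows.tolist(), cols.tolist()))
    off_diagonal = ~np.array(
        [(ia, ib) in matched for ia, ib in zip(inv_a, inv_b)]
    )
    disagreement_ids = frozenset(int(i) for i in ids[off_diagonal])
    n_dis = len(disagreement_ids)
    return PartitionComparison(
        equivalent=n_dis == 0,
        disagreement_ids=disagreement_ids,
        n_disagreements=n_dis,
        rand_index=float(rand_score(a, b)),
        nmi=float(normalized_mutual_info_score(a, b, average_method="arithmetic")),
    )


def is_symmetric_partition(
    p: Partition, symmetry: SymmetryMap
) -> tuple[bool, list[tuple[int, int]]]:
    """True iff every left/right pair is co-assigned; else list the violators."""
    if symmetry.covered_ids() != frozenset(p.assignment):
        raise DataError("symmetry map and partition cover different node sets")
    violating = [
        (a, b) for a, b in symmetry.pairs if p.assignment[a] != p.assignment[b]
    ]
    return not violating, violating


@dataclass(frozen=True)
class ConsensusResult:
    modal_partition: Partition
    support: float
    per_node_stability: Dict[int, float]


def consensus_partition(results: Sequence[DetectionResult]) -> ConsensusResult:
    """Modal partition of an ensemble, up to label permutation.

    The mode is the largest label-equivalence class; ties break toward the
    class with higher mean Q, then first occurrence.  Per-node stability is
    the fraction of runs assigning the node to its modal community under
    each run's best label matching against the mode.
    """
    if not results:
        raise DataError("consensus of an empty ensemble")
    keys = []
    for r in results:
        canon = r.partition.canonical()
        keys.append(tuple(sorted(canon.assignment.items())))
        if set(r.partition.assignment) != set(results[0].partition.assignment):
            raise DataError("ensemble partitions cover different node sets")
    counts = Counter(keys)
    mean_q: dict[tuple, float] = {}
    first: dict[tuple, int] = {}
    for idx, (key, r) in enumerate(zip(keys, results)):
        mean_q.setdefault(key, 0.0)
        mean_q[key] += r.Q
        first.setdefault(key, idx)
    modal_key = min(
        counts,
        key=lambda k: (-counts[k], -mean_q[k] / counts[k], first[k]),
    )
    modal = Partition(dict(modal_key))
    support = counts[modal_key] / len(results)

    ids = sorted(modal.assignment)
    agree = {i: 0 for i in ids}
    for r in results:
        cmp = compare_partitions(r.partition, modal)
        for i in ids:
            if i not in cmp.disagreement_ids:
                agree[i] += 1
    stability = {i: agree[i] / len(results) for i in ids}
    return ConsensusResult(modal, support, stability)


@dataclass(frozen=True)
class ModuleReport:
    """Summary of one community: membership by node class and edge counts."""

    label: int
    size: int
    members_by_class: Dict[str, tuple[str, ...]]
    internal_edges: int
    external_edges: int


def module_summary(
    network: AnatomicalNetwork, partition: Partition
) -> list[ModuleReport]:
    """Per-community membership (grouped by node class) and edge counts."""
    labels = partition.labels_for(network)
    A = np.asarray(network.adjacency)
    reports = []
    for c in sorted(np.unique(labels)):
        mask = labels == c
        ids = np.flatnonzero(mask) + 1
        by_class: dict[str, list[str]] = {}
        for i in ids:
            rec = network.node(int(i))
            by_class.setdefault(rec.node_class or "unclassified", []).append(rec.name)
        internal = int(A[np.ix_(mask, mask)].sum()) // 2
        external = int(A[np.ix_(mask, ~mask)].sum())
        reports.append(
            ModuleReport(
                label=int(c),
                size=int(mask.sum()),
                members_by_class={k: tuple(v) for k, v in sorted(by_class.items())},
                internal_edges=internal,
                external_edges=external,
            )
        )
    return reports
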