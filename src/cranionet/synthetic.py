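"""Generator of bilaterally symmetric planted-partition networks.

The generator emulates the statistical structure the head analysis
assumes: a small number of planted modules (blocks), each made of
left/right node pairs plus unpaired axis nodes, with denser connectivity
inside a block (``p_in``) than between blocks (``p_out``).

With ``enforce_mirror=True`` edges are drawn once per *mirror orbit* of
node pairs and copied to the mirrored pair, so the left/right involution
is a graph automorphism of every generated network — the exact property
the symmetry-constrained detector exploits.  Axis nodes are fixed points
of the involution, and a cross edge inside a pair (left_i, right_i) forms
an orbit of size one.

The default block structure mirrors the packaged head network: two blocks
of (6 pairs + 5 axis) and (8 pairs + 6 axis) nodes, i.e. 17 + 22 = 39.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .modularity import Partition
from .network import AnatomicalNetwork, NodeRecord, SymmetryMap

__all__ = ["SyntheticSpec", "PlantedNetwork", "generate", "edge_density_check", "HEAD_LIKE_BLOCKS"]

#: block sizes (n_pairs, n_axis) matching the 17/22 module split of the head
HEAD_LIKE_BLOCKS: tuple[tuple[int, int], ...] = ((6, 5), (8, 6))


@dataclass(frozen=True)
class SyntheticSpec:
    """Planted-partition parameters.

    ``blocks`` lists (n_pairs, n_axis) per planted module.  Edges appear
    independently with probability ``p_in`` within a block and ``p_out``
    across blocks, subject to the mirror constraint when
    ``enforce_mirror`` is set.
    """

    blocks: tuple[tuple[int, int], ...] = HEAD_LIKE_BLOCKS
    p_in: float = 0.3
    p_out: float = 0.05
    enforce_mirror: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        if not self.blocks:
            raise DataError("at least one block is required")
        for n_pairs, n_axis in self.blocks:
            if n_pairs < 0 or n_axis < 0 or n_pairs + n_axis == 0:
                raise DataError("each block needs a nonnegative, nonempty size")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise DataError("need 0 <= p_out <= p_in <= 1")

    @property
    def n_nodes(self) -> int:
        return sum(2 * p + a for p, a in self.blocks)


@dataclass(frozen=True)
class PlantedNetwork:
    """A synthetic network bundled with its ground truth."""

    network: AnatomicalNetwork
    truth: Partition
    symmetry: SymmetryMap
    spec: SyntheticSpec = field(repr=False)


def generate(spec: SyntheticSpec) -> PlantedNetwork:
    """Draw one planted network; identical output for identical spec+seed."""
    nodes: list[NodeRecord] = []
    block_of: list[int] = []
    pairs: list[tuple[int, int]] = []
    axis: set[int] = set()
    nid = 0
    for b, (n_pairs, n_axis) in enumerate(spec.blocks, start=1):
        for p in range(1, n_pairs + 1):
            left, right = nid + 1, nid + 2
            nodes.append(
                NodeRecord(left, f"M{b}.P{p}.left", laterality="left", mirror_id=right)
            )
            nodes.append(
                NodeRecord(right, f"M{b}.P{p}.right", laterality="right", mirror_id=left)
            )
            pairs.append((left, right))
            block_of += [b, b]
            nid += 2
        for a in range(1, n_axis + 1):
            nid += 1
            nodes.append(NodeRecord(nid, f"M{b}.A{a}"))
            axis.add(nid)
            block_of.append(b)

    n = nid
    blocks_arr = np.array(block_of)
    mirror = {i: i for i in axis}
    for a, b in pairs:
        mirror[a], mirror[b] = b, a

    rng = np.random.default_rng(spec.seed)
    A = np.zeros((n, n), dtype=np.int8)
    drawn: dict[tuple[int, int], int] = {}
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            p = spec.p_in if blocks_arr[i - 1] == blocks_arr[j - 1] else spec.p_out
            if spec.enforce_mirror:
                mi, mj = mirror[i], mirror[j]
                rep = min((i, j), (min(mi, mj), max(mi, mj)))
                if rep in drawn:
                    edge = drawn[rep]
                else:
                    edge = int(rng.random() < p)
                    drawn[rep] = edge
            else:
                edge = int(rng.random() < p)
            A[i - 1, j - 1] = A[j - 1, i - 1] = edge

    network = AnatomicalNetwork(nodes, A)
    truth = Partition({i: blocks_arr[i - 1] for i in range(1, n + 1)})
    symmetry = SymmetryMap(tuple(pairs), frozenset(axis))
    return PlantedNetwork(network, truth, symmetry, spec)


def edge_density_check(
    planted: PlantedNetwork,
) -> tuple[float, Optional[float]]:
    """Empirical (within-block, between-block) edge densities.

    The between-block density is ``None`` for a single-block spec.
    """
    labels = planted.truth.labels_for(planted.network)
    A = np.asarray(planted.network.adjacency)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    within_mask = same[iu]
    within = float(A[iu][within_mask].mean()) if within_mask.any() else 0.0
    between_pairs = ~within_mask
    if not between_pairs.any():
        return within, None
    return within, float(A[iu][between_pairs].mean())
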