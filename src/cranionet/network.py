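"""Graph data model and file I/O for anatomical networks.

An anatomical network is a labeled, undirected, binary graph: nodes are
anatomical units (brain subdivisions, bones), edges are physical contacts
or peripheral-nerve connections.  Bilateral anatomy is captured by a
:class:`SymmetryMap` pairing each left element with its right counterpart;
unpaired midline elements sit on the symmetry axis and are fixed points of
the mirror involution.

Supported on-disk formats:

* square 0/1 adjacency matrix (CSV or TSV, optional label header row and
  column, blank cells read as 0);
* two-column undirected edge list (isolated nodes as one-column rows);
* GraphML via :mod:`networkx`, with node attributes ``node_class``,
  ``laterality`` and ``mirror`` carried along.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import DataError

__all__ = [
    "NodeRecord",
    "AnatomicalNetwork",
    "SymmetryMap",
    "MatrixReadReport",
    "NamingConvention",
    "read_adjacency_matrix",
    "read_edge_list",
    "read_graphml",
    "write_network",
    "derive_symmetry_map",
    "read_symmetry_csv",
    "write_symmetry_csv",
]

CENTRAL_NERVOUS = "central_nervous"
SKELETAL = "skeletal"


@dataclass(frozen=True)
class NodeRecord:
    """One anatomical unit.

    ``id`` is the 1-based row index of the node in its adjacency matrix.
    ``mirror_id`` points to the contralateral partner for left/right nodes
    and is ``None`` exactly for midline (axis) nodes.
    """

    id: int
    name: str
    node_class: Optional[str] = None
    laterality: str = "midline"
    mirror_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right", "midline"):
            raise DataError(f"invalid laterality {self.laterality!r}")
        if (self.laterality == "midline") != (self.mirror_id is None):
            raise DataError(
                f"node {self.name!r}: laterality {self.laterality!r} is "
                f"inconsistent with mirror_id={self.mirror_id!r}"
            )


class AnatomicalNetwork:
    """Labeled, undirected, binary graph with dense adjacency storage.

    Node ids are the contiguous range ``1..n`` in node-list order; the
    adjacency matrix is validated to be symmetric, 0/1, and hollow
    (zero diagonal).
    """

    def __init__(self, nodes: Sequence[NodeRecord], adjacency: np.ndarray):
        nodes = list(nodes)
        A = np.asarray(adjacency)
        n = len(nodes)
        if A.shape != (n, n):
            raise DataError(f"adjacency shape {A.shape} does not match {n} nodes")
        if not np.isin(A, (0, 1)).all():
            raise DataError("adjacency entries must be 0 or 1")
        A = A.astype(np.int8)
        if (A != A.T).any():
            raise DataError("adjacency must be symmetric")
        if A.diagonal().any():
            raise DataError("adjacency must have a zero diagonal")
        for pos, rec in enumerate(nodes, start=1):
            if rec.id != pos:
                raise DataError(f"node ids must be 1..n in order; got {rec.id} at position {pos}")
        names = [rec.name for rec in nodes]
        if len(set(names)) != n:
            raise DataError("node names must be unique")
        # mirror relation must be an involution consistent with laterality
        by_id = {rec.id: rec for rec in nodes}
        for rec in nodes:
            if rec.mirror_id is not None:
                other = by_id.get(rec.mirror_id)
                if other is None or other.mirror_id != rec.id:
                    raise DataError(f"mirror of node {rec.name!r} is not an involution")
                if {rec.laterality, other.laterality} != {"left", "right"}:
                    raise DataError(f"mirrored nodes {rec.name!r}/{other.name!r} must be left/right")
        self._nodes = tuple(nodes)
        self._A = A
        self._A.setflags(write=False)
        self._name_to_id = {rec.name: rec.id for rec in nodes}

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> tuple[NodeRecord, ...]:
        return self._nodes

    @property
    def n(self) -> int:
        return len(self._nodes)

    @property
    def adjacency(self) -> np.ndarray:
        """Read-only n x n int8 adjacency matrix (A_ij)."""
        return self._A

    @property
    def degrees(self) -> np.ndarray:
        """Degree k_i per node, in node order."""
        return self._A.sum(axis=1).astype(np.int64)

    @property
    def m(self) -> int:
        """Number of edges; equals half the degree sum."""
        return int(self._A.sum()) // 2

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(rec.name for rec in self._nodes)

    def id_of(self, name: str) -> int:
        try:
            return self._name_to_id[name]
        except KeyError:
            raise DataError(f"unknown node name {name!r}") from None

    def name_of(self, node_id: int) -> str:
        return self._nodes[node_id - 1].name

    def node(self, node_id: int) -> NodeRecord:
        return self._nodes[node_id - 1]

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self._A[i - 1, j - 1])

    def neighbors(self, node_id: int) -> tuple[int, ...]:
        return tuple(int(j) + 1 for j in np.flatnonzero(self._A[node_id - 1]))

    def edges(self) -> Iterator[tuple[int, int]]:
        """Undirected edges as (i, j) id pairs with i < j."""
        iu, ju = np.triu_indices(self.n, k=1)
        mask = self._A[iu, ju] > 0
        for i, j in zip(iu[mask] + 1, ju[mask] + 1):
            yield int(i), int(j)

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx()) if self.n else True

    # -- constructors / converters ---------------------------------------
    @classmethod
    def from_edges(
        cls,
        names: Sequence[str],
        edges: Iterable[tuple[str, str] | tuple[int, int]],
        nodes: Optional[Sequence[NodeRecord]] = None,
    ) -> "AnatomicalNetwork":
        """Build a network from node names and undirected edges.

        Edges may reference nodes by name or by 1-based id.
        """
        names = list(names)
        if nodes is None:
            nodes = [NodeRecord(i + 1, nm) for i, nm in enumerate(names)]
        idx = {nm: i for i, nm in enumerate(names)}
        A = np.zeros((len(names), len(names)), dtype=np.int8)
        for u, v in edges:
            i = idx[u] if isinstance(u, str) else u - 1
            j = idx[v] if isinstance(v, str) else v - 1
            if i == j:
                raise DataError(f"self-loop on node {u!r}")
            A[i, j] = A[j, i] = 1
        return cls(nodes, A)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for rec in self._nodes:
            attrs = {"laterality": rec.laterality}
            if rec.node_class is not None:
                attrs["node_class"] = rec.node_class
            if rec.mirror_id is not None:
                attrs["mirror"] = self.name_of(rec.mirror_id)
            g.add_node(rec.name, **attrs)
        g.add_edges_from((self.name_of(i), self.name_of(j)) for i, j in self.edges())
        return g

    def same_topology(self, other: "AnatomicalNetwork") -> bool:
        """True if both networks have the same label set and edge set."""
        if set(self.names) != set(other.names):
            return False
        mine = {frozenset((self.name_of(i), self.name_of(j))) for i, j in self.edges()}
        theirs = {frozenset((other.name_of(i), other.name_of(j))) for i, j in other.edges()}
        return mine == theirs

    def __repr__(self) -> str:
        return f"AnatomicalNetwork(n={self.n}, m={self.m})"


@dataclass(frozen=True)
class SymmetryMap:
    """Bilateral structure: left/right pairs plus axis (fixed-point) nodes.

    Pairs and axis ids must partition the node-id set of the network the
    map describes; validation is performed by :meth:`validate`.
    """

    pairs: tuple[tuple[int, int], ...]
    axis_ids: frozenset[int]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        norm = tuple(sorted((min(a, b), max(a, b)) for a, b in self.pairs))
        object.__setattr__(self, "pairs", norm)
        for a, b in norm:
            if a == b:
                raise DataError(f"node {a} paired with itself")
            for x in (a, b):
                if x in seen or x in self.axis_ids:
                    raise DataError(f"node {x} appears more than once in symmetry map")
                seen.add(x)

    @property
    def mirror(self) -> dict[int, int]:
        """The involution as a dict; axis nodes map to themselves."""
        mu = {i: i for i in self.axis_ids}
        for a, b in self.pairs:
            mu[a], mu[b] = b, a
        return mu

    def covered_ids(self) -> frozenset[int]:
        return frozenset(self.mirror)

    def validate(self, network: AnatomicalNetwork) -> None:
        want = frozenset(range(1, network.n + 1))
        have = self.covered_ids()
        if have != want:
            raise DataError(
                f"symmetry map covers {len(have)} ids, network has {network.n}"
            )

    @classmethod
    def from_nodes(cls, nodes: Sequence[NodeRecord]) -> "SymmetryMap":
        pairs = {
            (min(r.id, r.mirror_id), max(r.id, r.mirror_id))
            for r in nodes
            if r.mirror_id is not None
        }
        axis = frozenset(r.id for r in nodes if r.mirror_id is None)
        return cls(tuple(sorted(pairs)), axis)


@dataclass
class MatrixReadReport:
    """What happened while reading an adjacency matrix file."""

    n_nodes: int
    n_edges: int
    asymmetric_cells: list[tuple[int, int]] = field(default_factory=list)
    symmetrization_policy: str = "union"
    nonzero_diagonal: list[int] = field(default_factory=list)


_POLICIES = ("union", "intersection", "strict")


def _parse_cell(raw: str, where: str) -> int:
    s = raw.strip()
    if s == "":
        return 0
    if s in ("0", "1"):
        return int(s)
    raise DataError(f"matrix cell {where} must be 0, 1 or blank; got {raw!r}")


def _sniff_rows(path: Path) -> list[list[str]]:
    text = path.read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    return [row for row in csv.reader(text.splitlines(), delimiter=delim) if row]


def read_adjacency_matrix(
    path: str | Path,
    policy: str = "union",
    labels: Optional[Sequence[str]] = None,
) -> tuple[AnatomicalNetwork, MatrixReadReport]:
    """Read a square 0/1 matrix (CSV or TSV) into a network.

    A leading header row plus label column is detected automatically.
    Asymmetric cells are resolved by ``policy``: ``union`` keeps an edge if
    either triangle has a 1, ``intersection`` requires both, ``strict``
    refuses the file.  Every asymmetric cell and any nonzero diagonal entry
    is recorded in the returned :class:`MatrixReadReport`.
    """
    if policy not in _POLICIES:
        raise DataError(f"unknown symmetrization policy {policy!r}")
    path = Path(path)
    if not path.exists():
        raise DataError(f"matrix file not found: {path}")
    rows = _sniff_rows(path)
    if not rows:
        raise DataError(f"empty matrix file: {path}")

    def _is_value(cell: str) -> bool:
        return cell.strip() in ("", "0", "1")

    # labeled iff the corner cell is no 0/1 value and some label cell is text
    corner_free = not rows[0][0].strip() or not _is_value(rows[0][0])
    any_text_label = not all(_is_value(c) for c in rows[0][1:]) or not all(
        _is_value(r[0]) for r in rows[1:]
    )
    has_header = corner_free and any_text_label
    if has_header:
        file_labels = [c.strip() for c in rows[0][1:]]
        body = rows[1:]
        row_labels = [r[0].strip() for r in body]
        if row_labels != file_labels:
            raise DataError("matrix row labels do not match column labels")
        cells = [r[1:] for r in body]
    else:
        file_labels = None
        cells = rows

    n = len(cells)
    if any(len(r) != n for r in cells):
        raise DataError("matrix is not square")
    use_labels = list(labels) if labels is not None else file_labels
    if use_labels is None:
        use_labels = [str(i) for i in range(1, n + 1)]
    if len(use_labels) != n:
        raise DataError(f"{len(use_labels)} labels for a {n}x{n} matrix")
    if len(set(use_labels)) != n:
        raise DataError("duplicate node labels")

    raw = np.empty((n, n), dtype=np.int8)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            raw[i, j] = _parse_cell(cell, f"({i + 1},{j + 1})")

    report = MatrixReadReport(n_nodes=n, n_edges=0, symmetrization_policy=policy)
    report.nonzero_diagonal = [int(i) + 1 for i in np.flatnonzero(raw.diagonal())]
    np.fill_diagonal(raw, 0)
    iu, ju = np.triu_indices(n, k=1)
    bad = raw[iu, ju] != raw[ju, iu]
    report.asymmetric_cells = [
        (int(i) + 1, int(j) + 1) for i, j in zip(iu[bad], ju[bad])
    ]
    if policy == "strict" and report.asymmetric_cells:
        raise DataError(
            f"strict read: {len(report.asymmetric_cells)} asymmetric cell(s), "
            f"first at {report.asymmetric_cells[0]}"
        )
    if policy == "intersection":
        A = (raw & raw.T).astype(np.int8)
    else:
        A = (raw | raw.T).astype(np.int8)
    nodes = [NodeRecord(i + 1, nm) for i, nm in enumerate(use_labels)]
    net = AnatomicalNetwork(nodes, A)
    report.n_edges = net.m
    # connectivity is not required for modularity analysis, only flagged
    if net.m > 0 and not net.is_connected():
        logging.getLogger(__name__).warning(
            "network read from %s is not connected", path
        )
    return net, report


def read_edge_list(path: str | Path) -> AnatomicalNetwork:
    """Read a two-column undirected edge list (one-column rows = isolated nodes)."""
    rows = _sniff_rows(Path(path))
    names: list[str] = []
    seen: set[str] = set()
    edges: list[tuple[str, str]] = []
    for row in rows:
        fields = [c.strip() for c in row if c.strip()]
        if not fields:
            continue
        if len(fields) > 2:
            raise DataError(f"edge list row has {len(fields)} fields: {row!r}")
        for nm in fields:
            if nm not in seen:
                seen.add(nm)
                names.append(nm)
        if len(fields) == 2:
            edges.append((fields[0], fields[1]))
    return AnatomicalNetwork.from_edges(names, edges)


def read_graphml(path: str | Path) -> AnatomicalNetwork:
    g = nx.read_graphml(Path(path))
    names = list(g.nodes)
    idx = {nm: i + 1 for i, nm in enumerate(names)}
    nodes = []
    for nm in names:
        attrs = g.nodes[nm]
        mirror_name = attrs.get("mirror")
        nodes.append(
            NodeRecord(
                id=idx[nm],
                name=nm,
                node_class=attrs.get("node_class"),
                laterality=attrs.get("laterality", "midline"),
                mirror_id=idx[mirror_name] if mirror_name else None,
            )
        )
    return AnatomicalNetwork.from_edges(names, list(g.edges), nodes=nodes)


def write_network(
    network: AnatomicalNetwork, path: str | Path, format: str = "matrix_csv"
) -> None:
    """Write a network so that re-reading reproduces its labels and edges."""
    path = Path(path)
    if format == "matrix_csv":
        with path.open("w", newline="") as f:
            w = csv.writer(f)
            w.writerow([""] + list(network.names))
            A = network.adjacency
            for i, nm in enumerate(network.names):
                w.writerow([nm] + [str(int(x)) for x in A[i]])
    elif format == "edge_list":
        connected = {i for e in network.edges() for i in e}
        with path.open("w", newline="") as f:
            w = csv.writer(f)
            for i, j in network.edges():
                w.writerow([network.name_of(i), network.name_of(j)])
            for rec in network.nodes:
                if rec.id not in connected:
                    w.writerow([rec.name])
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise DataError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# symmetry maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NamingConvention:
    """How left/right sidedness is marked in node names.

    The default recognizes a leading or trailing ``left``/``right`` word
    separated by space, dot, underscore or hyphen, case-insensitively —
    which covers names like ``"Left forebrain"`` and ``"Maxilla left"``.
    """

    left_patterns: tuple[str, ...] = (r"(?i)^left[ ._-]+", r"(?i)[ ._-]+left$")
    right_patterns: tuple[str, ...] = (r"(?i)^right[ ._-]+", r"(?i)[ ._-]+right$")

    def side_of(self, name: str) -> tuple[Optional[str], str]:
        """Return (side, base-name); side is None for unmarked names."""
        for side, pats in (("left", self.left_patterns), ("right", self.right_patterns)):
            for k, pat in enumerate(pats):
                new = re.sub(pat, "", name)
                if new != name:
                    return side, f"{k}:{new}"
        return None, name


def derive_symmetry_map(
    network: AnatomicalNetwork,
    convention: NamingConvention = NamingConvention(),
) -> SymmetryMap:
    """Pair left/right nodes by name; everything unmarked goes on the axis.

    Raises :class:`DataError` if a side-marked node has no counterpart of
    the opposite side with the same base name.
    """
    left: dict[str, int] = {}
    right: dict[str, int] = {}
    axis: set[int] = set()
    for rec in network.nodes:
        side, base = convention.side_of(rec.name)
        if side is None:
            axis.add(rec.id)
        else:
            bucket = left if side == "left" else right
            if base in bucket:
                raise DataError(f"two {side} nodes share base name {base!r}")
            bucket[base] = rec.id
    unmatched = set(left) ^ set(right)
    if unmatched:
        missing = sorted(
            network.name_of(left.get(b) or right[b]) for b in unmatched
        )
        raise DataError(f"side-marked node(s) without a counterpart: {missing}")
    pairs = tuple(sorted((left[b], right[b]) for b in left))
    return SymmetryMap(pairs, frozenset(axis))


def read_symmetry_csv(path: str | Path, network: AnatomicalNetwork) -> SymmetryMap:
    """Two-column rows are left/right pairs; one-column rows are axis nodes."""
    pairs: list[tuple[int, int]] = []
    axis: set[int] = set()
    for row in _sniff_rows(Path(path)):
        fields = [c.strip() for c in row if c.strip()]
        if not fields:
            continue
        if len(fields) == 2:
            pairs.append((network.id_of(fields[0]), network.id_of(fields[1])))
        elif len(fields) == 1:
            axis.add(network.id_of(fields[0]))
        else:
            raise DataError(f"symmetry row has {len(fields)} fields: {row!r}")
    sym = SymmetryMap(tuple(pairs), frozenset(axis))
    sym.validate(network)
    return sym


def write_symmetry_csv(
    symmetry: SymmetryMap, network: AnatomicalNetwork, path: str | Path
) -> None:
    with Path(path).open("w", newline="") as f:
        w = csv.writer(f)
        for a, b in symmetry.pairs:
            left_first = (a, b)
            if network.node(a).laterality == "right":
                left_first = (b, a)
            w.writerow([network.name_of(left_first[0]), network.name_of(left_first[1])])
        for i in sorted(symmetry.axis_ids):
            w.writerow([network.name_of(i)])
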