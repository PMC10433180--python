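"""The packaged 39-node human CNS-craniofacial skeleton network.

The network has 39 anatomical nodes — 12 central-nervous (nine brain
subdivisions: left/right/central-axis portions of forebrain, midbrain and
hindbrain; three spinal-cord portions) and 27 craniofacial-skeleton nodes —
with 145 undirected binary links (peripheral-nerve supply or direct
contact).  It ships as a plain CSV adjacency matrix plus a node-metadata
table under ``cranionet/data/``.

Index-to-name mapping
---------------------
The source adjacency matrix is published by row index only, without an
index-to-name legend.  The mapping shipped here is **provisional**
(see :data:`MAPPING_STATUS`): it was reconstructed by combining

* the published module membership lists (which fix the two 17/22-node
  blocks and the identity of the one node the spectral method reassigns,
  the sphenoid),
* the network's unique nontrivial graph automorphism, which is exactly a
  bilateral mirror involution with 14 transpositions and 11 fixed points,
  and
* anatomical adjacency (e.g. the brain chain forebrain-midbrain-hindbrain-
  spinal cord, periorbital bones linking to both forebrain and hindbrain,
  the auditory ossicle chain ending at the hindbrain).

No quantitative result in this package depends on the naming: all
detection and comparison operate on indices, and the fixture partitions
are stated in the same provisional names.

The three published module-membership tables are available through
:func:`table_partition` keyed as ``"spinglass"`` (original detector),
``"leading_eigenvector"`` (spectral cross-check; sphenoid moves to the
posterior module) and ``"symmetric_spinglass"`` (symmetry-constrained
detector; identical membership to ``"spinglass"``).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import DataError
from .modularity import Partition
from .network import AnatomicalNetwork, NodeRecord, SymmetryMap, read_adjacency_matrix

__all__ = ["builtin_head_network", "table_partition", "MAPPING_STATUS", "TABLE_KEYS"]

#: The index-to-name mapping is reconstructed, not published; see module docstring.
MAPPING_STATUS = "provisional"

_ANTERIOR_SPINGLASS = (
    "Left forebrain",
    "Forebrain central axis",
    "Right forebrain",
    "Sphenoid",
    "Zygomatic left",
    "Zygomatic right",
    "Frontal",
    "Ethmoidal",
    "Nasal left",
    "Nasal right",
    "Maxilla left",
    "Maxilla right",
    "Lacrimal left",
    "Lacrimal right",
    "Palatine left",
    "Palatine right",
    "Vomer",
)

#: published anterior-module membership per detector (module 2 = the rest)
_ANTERIOR = {
    "spinglass": _ANTERIOR_SPINGLASS,
    # the spectral method reassigns exactly the sphenoid to the posterior module
    "leading_eigenvector": tuple(
        nm for nm in _ANTERIOR_SPINGLASS if nm != "Sphenoid"
    ),
    # the symmetry-constrained detector reproduces the original membership
    "symmetric_spinglass": _ANTERIOR_SPINGLASS,
}

TABLE_KEYS = tuple(_ANTERIOR)


def _data_path(name: str):
    return resources.files("cranionet.data").joinpath(name)


def builtin_head_network() -> tuple[AnatomicalNetwork, SymmetryMap]:
    """Load the packaged 39-node head network and its bilateral symmetry map.

    Returns the network (12 central-nervous + 27 skeletal nodes, 145 edges)
    and the symmetry map of 14 left/right pairs plus 11 axis nodes (the
    four central-axis CNS segments and seven unpaired midline bones).
    """
    with resources.as_file(_data_path("head_adjacency.csv")) as p:
        net, report = read_adjacency_matrix(p, policy="union")
    if report.asymmetric_cells or report.nonzero_diagonal:
        raise DataError("packaged head adjacency matrix is corrupted")
    meta = pd.read_csv(_data_path("head_nodes.csv"))
    if list(meta["name"]) != list(net.names):
        raise DataError("packaged node metadata does not match the adjacency matrix")
    nodes = [
        NodeRecord(
            id=int(r.id),
            name=r.name,
            node_class=r.node_class,
            laterality=r.laterality,
            mirror_id=None if pd.isna(r.mirror_id) else int(r.mirror_id),
        )
        for r in meta.itertuples()
    ]
    net = AnatomicalNetwork(nodes, np.asarray(net.adjacency))
    return net, SymmetryMap.from_nodes(nodes)


def table_partition(key: str, network: AnatomicalNetwork | None = None) -> Partition:
    """A published module-membership table as a two-community partition.

    ``key`` is one of :data:`TABLE_KEYS`.  Community 1 is the anterior
    (forebrain + mid/upper face) module, community 2 the posterior one.
    """
    if key not in _ANTERIOR:
        raise DataError(f"unknown table key {key!r}; choose from {TABLE_KEYS}")
    if network is None:
        network, _ = builtin_head_network()
    anterior = {network.id_of(nm) for nm in _ANTERIOR[key]}
    assignment = {
        i: (1 if i in anterior else 2) for i in range(1, network.n + 1)
    }
    return Partition(assignment)
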