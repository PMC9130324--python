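"""Heterogeneous multi-layer molecular network assembly.

Reads per-layer interaction edge tables (lncRNA-mRNA, miRNA-mRNA,
miRNA-lncRNA, TF-miRNA, TF-mRNA, protein-protein, ...), normalizes
identifiers, and merges the layers into one undirected heterogeneous
network over typed molecular nodes.  Nodes are keyed by the pair
(identifier, node_type) so that overlapping namespaces (a miRNA and a
gene sharing a raw string) stay distinct.

All layers are symmetrized: regulatory edges (TF->target, miRNA->target)
are biologically directed, but random-walk guilt-by-association needs
bidirectional reachability, so the merged network is undirected and
unweighted with per-edge layer provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Recognised molecule categories for typed nodes.
NODE_TYPES = ("mRNA", "miRNA", "lncRNA", "TF", "protein", "unknown")

#: Canonical layer names and the (source type, target type) they connect.
LAYER_TYPES: Mapping[str, tuple[str, str]] = {
    "lncRNA-mRNA": ("lncRNA", "mRNA"),
    "miRNA-mRNA": ("miRNA", "mRNA"),
    "miRNA-lncRNA": ("miRNA", "lncRNA"),
    "TF-miRNA": ("TF", "miRNA"),
    "TF-mRNA": ("TF", "mRNA"),
    "PPI": ("protein", "protein"),
}

_HEADER_TOKENS = {
    "source", "target", "from", "to", "layer", "source_id", "target_id",
    "gene1", "gene2", "node1", "node2", "id1", "id2", "layers",
}


class NetworkError(ValueError):
    """Raised for invalid network inputs (empty layers, bad identifiers)."""


class InvalidIdentifierError(NetworkError):
    """Raised when an identifier is empty after normalization."""


def normalize_identifier(raw: str, node_type: str = "unknown") -> str:
    """Normalize a raw molecule identifier deterministically.

    Whitespace is stripped; miRNA names are case-folded to the lowercase
    ``hsa-mir-...`` convention so that ``hsa-miR-200c`` and
    ``hsa-mir-200c`` merge; gene/protein/TF/lncRNA symbols are
    upper-cased.  Unknown-type identifiers are only stripped.  The map is
    idempotent.

    Raises
    ------
    InvalidIdentifierError
        If ``raw`` is empty or whitespace-only.
    """
    if not isinstance(raw, str):
        raise InvalidIdentifierError(f"identifier must be a string, got {type(raw)!r}")
    ident = raw.strip()
    if not ident:
        raise InvalidIdentifierError("identifier is empty after stripping whitespace")
    if node_type == "miRNA":
        return ident.lower()
    if node_type in ("mRNA", "lncRNA", "TF", "protein"):
        return ident.upper()
    return ident


@dataclass(frozen=True, order=True)
class NodeId:
    """A typed molecular node: normalized identifier plus molecule type."""

    identifier: str
    node_type: str = "unknown"

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise NetworkError(
                f"unknown node type {self.node_type!r}; expected one of {NODE_TYPES}"
            )
        if not self.identifier or not self.identifier.strip():
            raise InvalidIdentifierError("NodeId identifier must be non-empty")

    @classmethod
    def make(cls, raw: str, node_type: str = "unknown") -> "NodeId":
        """Build a NodeId from a raw string, applying normalization."""
        return cls(normalize_identifier(raw, node_type), node_type)


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected interaction from a specific network layer."""

    source: NodeId
    target: NodeId
    layer: str

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise NetworkError(f"self-loop on {self.source.identifier!r} rejected")
        if not self.layer:
            raise NetworkError("layer label must be non-empty")


def _looks_like_header(cells: Sequence[str]) -> bool:
    return any(c.strip().lower() in _HEADER_TOKENS for c in cells[:3])


def read_edge_table(
    path: str | Path,
    layer: str,
    default_source_type: str = "unknown",
    default_target_type: str = "unknown",
) -> list[EdgeRecord]:
    """Parse a tab-separated edge table into EdgeRecords.

    Expected columns: source, target and an optional per-row layer label
    (which overrides ``layer``).  A header row is auto-detected by its
    first cells matching common column names.  Rows with empty
    identifiers and self-loops (after normalization) are skipped and the
    skip counts logged.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    NetworkError
        If no valid edge survives parsing ("empty layer").
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge table not found: {path}")
    frame = pd.read_csv(
        path, sep="\t", header=None, dtype=str, comment="#",
        skip_blank_lines=True, keep_default_na=False,
    )
    if frame.shape[1] < 2:
        raise NetworkError(f"{path}: edge table needs >=2 tab-separated columns")
    rows = frame.itertuples(index=False, name=None)
    first = frame.iloc[0].tolist()
    records: list[EdgeRecord] = []
    skipped_empty = 0
    skipped_loops = 0
    for i, row in enumerate(rows):
        if i == 0 and _looks_like_header(first):
            continue
        raw_src, raw_tgt = row[0], row[1]
        row_layer = row[2].strip() if len(row) > 2 and row[2].strip() else layer
        try:
            src = NodeId.make(raw_src, default_source_type)
            tgt = NodeId.make(raw_tgt, default_target_type)
        except InvalidIdentifierError:
            skipped_empty += 1
            continue
        if src == tgt:
            skipped_loops += 1
            continue
        records.append(EdgeRecord(src, tgt, row_layer))
    if skipped_empty or skipped_loops:
        logger.info(
            "%s [%s]: skipped %d rows with empty ids, %d self-loops",
            path.name, layer, skipped_empty, skipped_loops,
        )
    if not records:
        raise NetworkError(f"{path}: empty layer {layer!r} (no valid edges)")
    return records


@dataclass
class HeterogeneousNetwork:
    """Merged undirected multi-layer network with typed nodes.

    ``nodes`` is deterministically sorted by (identifier, node_type);
    ``edges`` maps index pairs (i, j) with i < j to the frozenset of
    layer labels the edge was observed in.
    """

    nodes: list[NodeId]
    edges: dict[tuple[int, int], frozenset[str]]
    node_index: dict[NodeId, int] = field(repr=False)

    @property
    def m(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def __contains__(self, node: NodeId) -> bool:
        return node in self.node_index

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.m, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> sp.csr_array:
        """Symmetric binary adjacency matrix in the node ordering."""
        if not self.edges:
            return sp.csr_array((self.m, self.m))
        ij = np.array(list(self.edges), dtype=np.int64)
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        data = np.ones(rows.size)
        return sp.csr_array(sp.coo_array((data, (rows, cols)), shape=(self.m, self.m)))

    def to_networkx(self):
        """Export as a networkx Graph; nodes carry a ``node_type`` attribute."""
        import networkx as nx

        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, node_type=node.node_type)
        for (i, j), layers in self.edges.items():
            g.add_edge(self.nodes[i], self.nodes[j], layers=sorted(layers))
        return g

    def find(self, identifier: str) -> list[NodeId]:
        """All nodes whose identifier matches (any molecule type)."""
        return [n for n in self.nodes if n.identifier == identifier]


def assemble_network(records: Iterable[EdgeRecord]) -> HeterogeneousNetwork:
    """Merge layered edge records into one heterogeneous network.

    The node set is the union of edge endpoints (isolated nodes cannot
    occur); duplicate undirected edges across layers collapse to one
    edge whose provenance is the set of contributing layers.  Node
    ordering is sorted, so assembly is order-independent.
    """
    records = list(records)
    if not records:
        raise NetworkError("cannot assemble a network from zero edge records")
    node_set: set[NodeId] = set()
    for rec in records:
        node_set.add(rec.source)
        node_set.add(rec.target)
    nodes = sorted(node_set)
    index = {node: i for i, node in enumerate(nodes)}
    layer_sets: dict[tuple[int, int], set[str]] = {}
    for rec in records:
        i, j = index[rec.source], index[rec.target]
        key = (i, j) if i < j else (j, i)
        layer_sets.setdefault(key, set()).add(rec.layer)
    edges = {key: frozenset(layers) for key, layers in layer_sets.items()}
    return HeterogeneousNetwork(nodes=nodes, edges=edges, node_index=index)


def write_network(
    network: HeterogeneousNetwork,
    edges_path: str | Path,
    nodes_path: str | Path,
) -> None:
    """Write the merged network as a TSV edge list plus a node table.

    The edge list has columns source, target, layers (comma-joined); the
    node table has identifier, node_type, degree.  Output is sorted and
    byte-stable, and round-trips through :func:`read_network`.
    """
    deg = network.degrees()
    edge_rows = []
    for (i, j), layers in sorted(network.edges.items()):
        edge_rows.append(
            (network.nodes[i].identifier, network.nodes[i].node_type,
             network.nodes[j].identifier, network.nodes[j].node_type,
             ",".join(sorted(layers)))
        )
    pd.DataFrame(
        edge_rows,
        columns=["source", "source_type", "target", "target_type", "layers"],
    ).to_csv(edges_path, sep="\t", index=False)
    pd.DataFrame(
        [(n.identifier, n.node_type, int(deg[i])) for i, n in enumerate(network.nodes)],
        columns=["identifier", "node_type", "degree"],
    ).to_csv(nodes_path, sep="\t", index=False)


def read_network(edges_path: str | Path) -> HeterogeneousNetwork:
    """Re-read a network written by :func:`write_network` (edge list only)."""
    frame = pd.read_csv(edges_path, sep="\t", dtype=str, keep_default_na=False)
    records: list[EdgeRecord] = []
    for row in frame.itertuples(index=False):
        src = NodeId.make(row.source, row.source_type)
        tgt = NodeId.make(row.target, row.target_type)
        for lab in row.layers.split(","):
            records.append(EdgeRecord(src, tgt, lab))
    return assemble_network(records)
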