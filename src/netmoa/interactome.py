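"""Signed directed protein interaction network.

The interactome is a directed graph whose nodes are proteins (opaque,
case-sensitive identifiers following the gene-symbol convention) and whose
edges carry a sign: ``+1`` for an activating interaction, ``-1`` for an
inhibiting one.  Signal flows along edge direction; neighborhood and
distance queries operate on the undirected skeleton, which is derived on
demand.

Two text dialects are supported for edge lists:

* three-column TSV: ``source<TAB>interaction<TAB>target``
* Cytoscape SIF:    ``source relation target [target2 ...]`` (whitespace)

Interaction tokens ``activates``, ``1`` and ``+1`` map to sign +1;
``inhibits`` and ``-1`` map to -1.  Lines starting with ``#`` are comments,
except a header of the form ``#node <name>`` which declares an isolated
node.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

UNREACHABLE = math.inf
"""Sentinel returned by :func:`shortest_path_hops` for disconnected pairs."""

_POSITIVE_TOKENS = {"activates", "1", "+1"}
_NEGATIVE_TOKENS = {"inhibits", "-1"}


class FormatError(ValueError):
    """An edge-list record could not be parsed."""


class ConflictError(ValueError):
    """Two records assign conflicting signs to the same ordered pair."""


class Interactome:
    """Signed directed protein graph.

    Invariants enforced at construction time: every edge endpoint is a
    node, at most one edge per ordered pair, signs are exactly ±1, and
    self-loops are rejected (the propagation update has no self-recurrence).
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()
        self._undirected: nx.Graph | None = None

    # -- construction -------------------------------------------------

    def add_node(self, protein: str) -> None:
        if not isinstance(protein, str) or not protein:
            raise ValueError(f"protein identifier must be a non-empty string, got {protein!r}")
        self._g.add_node(protein)
        self._undirected = None

    def add_edge(self, source: str, target: str, sign: int) -> None:
        if sign not in (-1, 1):
            raise ValueError(f"edge sign must be -1 or +1, got {sign!r}")
        if source == target:
            raise ValueError(f"self-loop rejected: {source!r}")
        if self._g.has_edge(source, target):
            existing = self._g.edges[source, target]["sign"]
            if existing != sign:
                raise ConflictError(
                    f"conflicting signs for edge ({source!r}, {target!r}): "
                    f"{existing} vs {sign}"
                )
            return  # duplicate identical record: deduplicate silently
        self.add_node(source)
        self.add_node(target)
        self._g.add_edge(source, target, sign=sign)
        self._undirected = None

    # -- views ---------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str, int]]:
        return frozenset((u, v, d["sign"]) for u, v, d in self._g.edges(data=True))

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def sign(self, source: str, target: str) -> int:
        return self._g.edges[source, target]["sign"]

    def has_edge(self, source: str, target: str) -> bool:
        return self._g.has_edge(source, target)

    def directed_view(self) -> nx.DiGraph:
        """The underlying directed graph (do not mutate)."""
        return self._g

    def undirected_view(self) -> nx.Graph:
        """Undirected skeleton, cached until the next mutation."""
        if self._undirected is None:
            self._undirected = self._g.to_undirected(as_view=False)
        return self._undirected

    def in_edges(self, node: str) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) for u, v, d in self._g.in_edges(node, data=True)]

    def sorted_nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def sorted_edges(self) -> list[tuple[str, str, int]]:
        return sorted((u, v, d["sign"]) for u, v, d in self._g.edges(data=True))

    def __contains__(self, protein: str) -> bool:
        return protein in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Interactome(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def _token_sign(token: str, lineno: int, path: str) -> int:
    if token in _POSITIVE_TOKENS:
        return 1
    if token in _NEGATIVE_TOKENS:
        return -1
    raise FormatError(f"{path}:{lineno}: unknown interaction token {token!r}")


def read_edge_list(path: str, dialect: str = "tsv") -> Interactome:
    """Read a signed edge list in the ``tsv`` or ``sif`` dialect."""
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'sif')")
    net = Interactome()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line[1:].split()
                if len(fields) == 2 and fields[0] == "node":
                    net.add_node(fields[1])
                continue
            if dialect == "tsv":
                fields = line.split("\t")
                if len(fields) != 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                    )
                source, token, targets = fields[0], fields[1], [fields[2]]
            else:
                fields = line.split()
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected 'source relation target...', got {line!r}"
                    )
                source, token, targets = fields[0], fields[1], fields[2:]
            sign = _token_sign(token, lineno, path)
            for target in targets:
                try:
                    net.add_edge(source, target, sign)
                except ConflictError as exc:
                    raise ConflictError(f"{path}:{lineno}: {exc}") from None
    return net


def write_edge_list(net: Interactome, path: str, dialect: str = "tsv") -> None:
    """Write an edge list; round-trips with :func:`read_edge_list`."""
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'sif')")
    sep = "\t" if dialect == "tsv" else " "
    connected = {u for u, _, _ in net.edges} | {v for _, v, _ in net.edges}
    with open(path, "w", encoding="utf-8") as fh:
        for node in net.sorted_nodes():
            if node not in connected:
                fh.write(f"#node {node}\n")
        for u, v, s in net.sorted_edges():
            token = "activates" if s == 1 else "inhibits"
            fh.write(f"{u}{sep}{token}{sep}{v}\n")


def extract_disease_subnetwork(
    net: Interactome, effectors: Iterable[str]
) -> tuple[Interactome, pd.DataFrame]:
    """Induced subgraph on the effectors plus their first neighbors.

    Neighborhood ignores edge direction.  Returns the subnetwork together
    with an annotation table (columns ``protein``, ``is_effector``).

    Raises ``KeyError`` naming any effector absent from the network and
    ``ValueError`` on an empty effector set.
    """
    effectors = set(effectors)
    if not effectors:
        raise ValueError("effector set is empty")
    missing = sorted(effectors - net.nodes)
    if missing:
        raise KeyError(f"effectors not in network: {missing}")
    skeleton = net.undirected_view()
    keep = set(effectors)
    for e in effectors:
        keep.update(skeleton.neighbors(e))
    sub = Interactome()
    for node in keep:
        sub.add_node(node)
    for u, v, s in net.edges:
        if u in keep and v in keep:
            sub.add_edge(u, v, s)
    annotation = pd.DataFrame(
        {
            "protein": sorted(keep),
            "is_effector": [p in effectors for p in sorted(keep)],
        }
    )
    return sub, annotation


def shortest_path_hops(net: Interactome, a: str, b: str) -> float:
    """Unweighted hop count between two proteins on the undirected skeleton.

    Returns ``0`` for ``a == b`` and the :data:`UNREACHABLE` sentinel
    (``math.inf``) for disconnected pairs.
    """
    for p in (a, b):
        if p not in net:
            raise KeyError(f"unknown protein {p!r}")
    if a == b:
        return 0
    try:
        return nx.shortest_path_length(net.undirected_view(), a, b)
    except nx.NetworkXNoPath:
        return UNREACHABLE


def hop_distances_from(net: Interactome, source: str) -> Mapping[str, int]:
    """All hop distances from ``source`` on the undirected skeleton (BFS)."""
    if source not in net:
        raise KeyError(f"unknown protein {source!r}")
    return nx.single_source_shortest_path_length(net.undirected_view(), source)
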