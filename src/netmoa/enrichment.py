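"""Hypergeometric over-representation analysis and Hausdorff clustering.

High-activity proteins (|predicted activity| strictly above a threshold,
default 0.8) form the foreground; each GMT protein set is tested for
over-representation against the complete model protein list with an
upper-tail hypergeometric test, Benjamini–Hochberg corrected.  Enriched
sets are then related to each other geometrically: the Hausdorff distance

    d_H(X, Y) = max( sup_x inf_y d(x, y), sup_y inf_x d(x, y) )

with d the unweighted hop distance on the interactome's undirected
skeleton, links sets whose members occupy the same network neighborhood.
Pairs within a distance cutoff (default 1.2) become edges of the
enrichment network.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .interactome import UNREACHABLE, Interactome
from .propagation import ActivityProfile

FOREGROUND_THRESHOLD = 0.8
DEFAULT_MIN_SET_SIZE = 10
DEFAULT_MAX_SET_SIZE = 200
DEFAULT_Q_THRESHOLD = 0.001
DEFAULT_MAX_HAUSDORFF = 1.2


@dataclass(frozen=True)
class ProteinSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"protein set {self.set_id!r} is empty")


@dataclass
class ProteinSetCollection:
    sets: dict[str, ProteinSet]
    background: frozenset[str]


def read_gmt(path: str, background: Iterable[str]) -> ProteinSetCollection:
    """GMT: set-id TAB description TAB member TAB member ...

    ``background`` is the complete model protein list used as the
    reference for the tests.
    """
    sets: dict[str, ProteinSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT record needs id, description, members")
            set_id, name, members = fields[0], fields[1], fields[2:]
            sets[set_id] = ProteinSet(set_id=set_id, name=name, members=frozenset(members))
    return ProteinSetCollection(sets=sets, background=frozenset(background))


def write_gmt(collection: ProteinSetCollection, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(collection.sets):
            ps = collection.sets[set_id]
            fh.write("\t".join([ps.set_id, ps.name, *sorted(ps.members)]) + "\n")


def select_foreground(
    profile: ActivityProfile | Mapping[str, float],
    threshold: float = FOREGROUND_THRESHOLD,
) -> set[str]:
    """Proteins with |activity| strictly above the threshold."""
    activity = profile.activity if isinstance(profile, ActivityProfile) else profile
    return {p for p, o in activity.items() if abs(o) > threshold}


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K)) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    overlap: int  # k
    foreground_size: int  # n
    set_size: int  # K (restricted to background)
    background_size: int  # N
    p_value: float
    q_value: float
    significant: bool


def run_enrichment(
    foreground: Iterable[str],
    collection: ProteinSetCollection,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment with BH correction.

    Sets outside [min_size, max_size] (sizes counted within the
    background) are dropped BEFORE testing, so they do not enter the BH
    family.  All tested sets are returned sorted by (q, p); the
    ``significant`` flag marks q <= q_threshold.
    """
    foreground = set(foreground)
    stray = foreground - collection.background
    if stray:
        raise ValueError(
            f"foreground proteins absent from background: {sorted(stray)[:5]}"
        )
    if not foreground:
        warnings.warn("empty foreground: no enrichment performed", UserWarning)
        return []
    N = len(collection.background)
    n = len(foreground)
    tested: list[tuple[ProteinSet, int, int, float]] = []
    for set_id in sorted(collection.sets):
        ps = collection.sets[set_id]
        members = ps.members & collection.background
        K = len(members)
        if K < min_size or K > max_size:
            continue
        k = len(members & foreground)
        tested.append((ps, k, K, hypergeometric_p(k, n, K, N)))
    if not tested:
        return []
    _, qvalues, _, _ = multipletests([t[3] for t in tested], method="fdr_bh")
    results = [
        EnrichmentResult(
            set_id=ps.set_id,
            name=ps.name,
            overlap=k,
            foreground_size=n,
            set_size=K,
            background_size=N,
            p_value=float(p),
            q_value=float(q),
            significant=bool(q <= q_threshold),
        )
        for (ps, k, K, p), q in zip(tested, qvalues)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_id))
    return results


def hausdorff_distance(
    X: Iterable[str],
    Y: Iterable[str],
    d: Callable[[str, str], float],
) -> float:
    """Symmetric Hausdorff distance between two point sets under metric d.

    Any required pair at infinite distance makes the result infinite.
    """
    X, Y = list(X), list(Y)
    if not X or not Y:
        raise ValueError("Hausdorff distance is undefined for empty sets")
    forward = max(min(d(x, y) for y in Y) for x in X)
    backward = max(min(d(x, y) for x in X) for y in Y)
    return max(forward, backward)


def graph_hop_metric(net: Interactome) -> Callable[[str, str], float]:
    """Hop-distance metric on the undirected skeleton, with BFS caching."""
    cache: dict[str, Mapping[str, int]] = {}
    skeleton = net.undirected_view()

    def d(a: str, b: str) -> float:
        if a == b:
            return 0.0
        if a not in cache:
            cache[a] = nx.single_source_shortest_path_length(skeleton, a)
        return float(cache[a].get(b, UNREACHABLE))

    return d


def _set_distance(
    members_a: Sequence[str],
    members_b: Sequence[str],
    d: Callable[[str, str], float],
    mode: str,
) -> float:
    if mode == "hausdorff":
        return hausdorff_distance(members_a, members_b, d)
    if mode == "mean_min":
        # symmetrized mean of directed nearest-member distances; smoother
        # than the max-based Hausdorff, same 0-at-identity behavior
        fwd = np.mean([min(d(a, b) for b in members_b) for a in members_a])
        bwd = np.mean([min(d(a, b) for a in members_a) for b in members_b])
        return float((fwd + bwd) / 2.0)
    raise ValueError(f"unknown distance_mode {mode!r}")


def enrichment_network(
    results: Sequence[EnrichmentResult],
    net: Interactome,
    collection: ProteinSetCollection,
    max_distance: float = DEFAULT_MAX_HAUSDORFF,
    distance_mode: str = "hausdorff",
) -> list[tuple[str, str, float]]:
    """All unordered pairs of enriched sets within the distance cutoff.

    Set members absent from the interactome are ignored; a set with no
    member in the network is excluded with a warning.
    """
    if len(results) < 2:
        raise ValueError("need at least two enriched sets to build a network")
    d = graph_hop_metric(net)
    members: dict[str, list[str]] = {}
    for r in results:
        present = sorted(collection.sets[r.set_id].members & net.nodes)
        if not present:
            warnings.warn(
                f"enriched set {r.set_id!r} has no member in the network; excluded",
                UserWarning,
            )
            continue
        members[r.set_id] = present
    edges: list[tuple[str, str, float]] = []
    for a, b in itertools.combinations(sorted(members), 2):
        dist = _set_distance(members[a], members[b], d, distance_mode)
        if dist <= max_distance:
            edges.append((a, b, dist))
    return edges


def write_enrichment_table(results: Sequence[EnrichmentResult], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_id\tname\toverlap\tforeground\tset_size\tbackground\tp\tq\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.set_id}\t{r.name}\t{r.overlap}\t{r.foreground_size}\t"
                f"{r.set_size}\t{r.background_size}\t{r.p_value:.6g}\t"
                f"{r.q_value:.6g}\t{int(r.significant)}\n"
            )


def write_enrichment_network(
    edges: Sequence[tuple[str, str, float]],
    results: Sequence[EnrichmentResult],
    path_edges: str,
    path_nodes: str,
) -> None:
    """Edge TSV plus a node attribute table (overlap size, FDR) for
    Cytoscape-style import."""
    with open(path_edges, "w", encoding="utf-8") as fh:
        fh.write("set_a\tset_b\tdistance\n")
        for a, b, dist in sorted(edges):
            fh.write(f"{a}\t{b}\t{dist:.10g}\n")
    with open(path_nodes, "w", encoding="utf-8") as fh:
        fh.write("set_id\tname\toverlap\tq\n")
        for r in results:
            fh.write(f"{r.set_id}\t{r.name}\t{r.overlap}\t{r.q_value:.6g}\n")
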