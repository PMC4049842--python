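"""Genotype networks over binary haplotype strings and their four statistics.

A genotype network has one node per distinct haplotype observed in a sample
and an undirected edge between every pair of nodes at Hamming distance
exactly one — a single mutational step.  The full genotype space over k
biallelic SNVs is the k-dimensional hypercube; an observed network is the
subgraph induced by the haplotypes present in the sample.

Four statistics summarise a network:

* **number of vertices** — distinct haplotypes (Nei's Dh count of types);
  with the average path length, it measures how far the sample extends
  through genotype space;
* **average path length** — mean shortest-path length over connected node
  pairs (pairs in different components are excluded; undefined when no
  connected pair exists);
* **number of components** — maximal connected subgraphs, isolated nodes
  included; a fragmented network has many;
* **average degree** — mean neighbour count over *all* nodes, isolated nodes
  contributing zero (equivalently 2|E|/|V|); with the component count, a
  measure of the network's stability to point mutations.

Edge construction is sub-quadratic: each node's k bit-flip candidates are
probed against a hash index of observed nodes, O(V·k) expected, versus the
O(V²·k) all-pairs scan kept here as a testing oracle.  Internally nodes are
packed into integers (one bit per SNV); the string representation is the
public surface.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenotypeNetwork",
    "NetworkProperties",
    "hamming_neighbors",
    "build_network",
    "build_network_bruteforce",
    "n_vertices",
    "average_path_length",
    "n_components",
    "average_degree",
    "properties",
    "to_networkx",
    "write_edgelist",
    "write_graphml",
]

MAX_K = 63  # nodes are packed into uint64 bit masks


def hamming_neighbors(genotype: str) -> list[str]:
    """All k single-bit-flip mutants of a genotype string.

    These are the candidate neighbours in genotype space: a random point
    mutation of the genotype yields exactly one of them.
    """
    _validate_strings([genotype])
    return [
        genotype[:i] + ("1" if genotype[i] == "0" else "0") + genotype[i + 1 :]
        for i in range(len(genotype))
    ]


def _validate_strings(genotypes: Sequence[str]) -> int:
    if len(genotypes) == 0:
        raise ValueError("at least one genotype string is required")
    k = len(genotypes[0])
    if k == 0:
        raise ValueError("genotype strings must be non-empty")
    if k > MAX_K:
        raise ValueError(f"genotype length {k} exceeds the supported maximum of {MAX_K}")
    for g in genotypes:
        if len(g) != k:
            raise ValueError(f"mixed genotype lengths: {len(g)} vs {k}")
        if set(g) - {"0", "1"}:
            raise ValueError(f"genotype strings must be binary, got {g!r}")
    return k


def _pack(genotypes: Iterable[str]) -> list[int]:
    # bit i of the integer is site i (leftmost character = bit 0)
    return [int(g[::-1], 2) for g in genotypes]


def _unpack(value: int, k: int) -> str:
    return format(value, f"0{k}b")[::-1]


def _adjacency(nodes: Iterable[int], k: int) -> dict[int, list[int]]:
    """Hamming-1 adjacency via per-node bit flips against a membership index."""
    node_set = set(nodes)
    adj: dict[int, list[int]] = {u: [] for u in node_set}
    for u in node_set:
        for i in range(k):
            v = u ^ (1 << i)
            if v > u and v in node_set:
                adj[u].append(v)
                adj[v].append(u)
    return adj


@dataclass
class GenotypeNetwork:
    """Distinct genotypes, Hamming-1 edges, and per-node haplotype counts."""

    k: int
    node_counts: dict[str, int]
    _adj: dict[int, list[int]]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.node_counts)

    @property
    def edges(self) -> list[tuple[str, str]]:
        out = []
        for u, nbrs in self._adj.items():
            su = _unpack(u, self.k)
            for v in nbrs:
                if v > u:
                    out.append(tuple(sorted((su, _unpack(v, self.k)))))
        return sorted(out)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def degree(self, genotype: str) -> int:
        return len(self._adj[_pack([genotype])[0]])


def build_network(genotypes: Sequence[str]) -> GenotypeNetwork:
    """Build the genotype network of a list of binary haplotype strings.

    Nodes are the distinct strings; edges join pairs at Hamming distance
    exactly one.  Duplicate input strings accumulate in ``node_counts`` but
    do not change the graph.
    """
    k = _validate_strings(genotypes)
    counts: dict[str, int] = {}
    for g in genotypes:
        counts[g] = counts.get(g, 0) + 1
    adj = _adjacency(_pack(counts), k)
    return GenotypeNetwork(k=k, node_counts=counts, _adj=adj)


def build_network_bruteforce(genotypes: Sequence[str]) -> GenotypeNetwork:
    """O(V^2 k) all-pairs construction; testing oracle for build_network."""
    k = _validate_strings(genotypes)
    counts: dict[str, int] = {}
    for g in genotypes:
        counts[g] = counts.get(g, 0) + 1
    nodes = _pack(counts)
    adj: dict[int, list[int]] = {u: [] for u in nodes}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if bin(u ^ v).count("1") == 1:
                adj[u].append(v)
                adj[v].append(u)
    return GenotypeNetwork(k=k, node_counts=counts, _adj=adj)


# ---------------------------------------------------------------------------
# properties

def n_vertices(net: GenotypeNetwork) -> int:
    return len(net.node_counts)


def average_degree(net: GenotypeNetwork) -> float:
    return 2.0 * net.n_edges / len(net.node_counts)


def _components(adj: dict[int, list[int]]) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    queue.append(v)
        comps.append(comp)
    return comps


def n_components(net: GenotypeNetwork) -> int:
    return len(_components(net._adj))


def average_path_length(net: GenotypeNetwork) -> float | None:
    """Mean shortest-path length over connected node pairs.

    Pairs in different components enter neither numerator nor denominator;
    ``None`` when no connected pair exists (single node or all isolated).
    """
    total, pairs = _apl_terms(net._adj)
    return total / pairs if pairs else None


def _apl_terms(adj: dict[int, list[int]]) -> tuple[int, int]:
    total = 0
    pairs = 0
    for comp in _components(adj):
        m = len(comp)
        if m < 2:
            continue
        for src in comp:
            dist = {src: 0}
            queue = deque([src])
            while queue:
                u = queue.popleft()
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        queue.append(v)
            total += sum(dist.values())
        pairs += m * (m - 1)
    # each unordered pair counted twice
    return total // 2 if pairs else 0, pairs // 2


@dataclass(frozen=True)
class NetworkProperties:
    """The four per-window statistics plus the vertices/components ratio."""

    n_vertices: int
    avg_path_length: float | None
    n_components: int
    avg_degree: float

    @property
    def vertices_per_component(self) -> float:
        return self.n_vertices / self.n_components

    def as_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "avg_path_length": (
                np.nan if self.avg_path_length is None else self.avg_path_length
            ),
            "n_components": self.n_components,
            "avg_degree": self.avg_degree,
            "vertices_per_component": self.vertices_per_component,
        }


PROPERTY_NAMES = (
    "n_vertices",
    "avg_path_length",
    "n_components",
    "avg_degree",
    "vertices_per_component",
)


def properties(genotypes: Sequence[str]) -> NetworkProperties:
    """Network properties of a haplotype sample; invariant to input order."""
    net = build_network(genotypes)
    return NetworkProperties(
        n_vertices=n_vertices(net),
        avg_path_length=average_path_length(net),
        n_components=n_components(net),
        avg_degree=average_degree(net),
    )


def properties_packed(values: np.ndarray, k: int) -> NetworkProperties:
    """Fast path for the genome scan: haplotypes already packed as integers
    (bit i = site i).  Semantics identical to :func:`properties`."""
    uniq = np.unique(values)
    adj = _adjacency((int(v) for v in uniq), k)
    v = len(adj)
    deg = sum(len(a) for a in adj.values()) / v
    comps = _components(adj)
    total, pairs = _apl_terms(adj)
    return NetworkProperties(
        n_vertices=v,
        avg_path_length=total / pairs if pairs else None,
        n_components=len(comps),
        avg_degree=deg,
    )


# ---------------------------------------------------------------------------
# export

def to_networkx(net: GenotypeNetwork):
    """The network as a networkx.Graph with 'count' node attributes."""
    import networkx as nx

    g = nx.Graph()
    for node, count in net.node_counts.items():
        g.add_node(node, count=count)
    g.add_edges_from(net.edges)
    return g


def write_edgelist(net: GenotypeNetwork, path: str) -> None:
    """Tab-separated edge list; isolated nodes listed on single-column lines."""
    isolated = {u for u, nbrs in net._adj.items() if not nbrs}
    with open(path, "w") as fh:
        for a, b in net.edges:
            fh.write(f"{a}\t{b}\n")
        for u in sorted(isolated):
            fh.write(f"{_unpack(u, net.k)}\n")


def write_graphml(net: GenotypeNetwork, path: str) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(net), path)
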