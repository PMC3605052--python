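"""Motif similarity networks and Markov clustering.

For one transcription-factor class at a time, a motif is connected to
every same-class motif that scores higher than its best-scoring
non-class motif; non-class scores thus act as a per-motif background
threshold.  Edges are unweighted and undirected; because the rule is
evaluated per motif, an edge is kept if it fires from *either*
endpoint (union semantics — an ``intersection`` mode is available).

Families are then extracted with the Markov Cluster algorithm (MCL):
self-loops are added, the adjacency matrix is column-normalized, and
expansion (matrix squaring) alternates with inflation (entrywise power
followed by column renormalization) until the matrix stops changing.
Clusters are read off the attractor rows of the converged matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

#: classes with fewer motifs than this are built but flagged
MIN_CLASS_SIZE = 5


@dataclass
class MotifNetwork:
    """Unweighted graph of same-class motifs."""

    class_label: str
    graph: nx.Graph
    below_analysis_threshold: bool = False

    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> List[Tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


@dataclass
class NetworkClustering:
    """A partition of network nodes produced by MCL."""

    clusters: List[Set[str]]
    inflation: float
    converged: bool = True

    @property
    def labels(self) -> Dict[str, int]:
        return {n: i for i, cl in enumerate(self.clusters) for n in cl}


def build_network(
    scores: pd.DataFrame,
    classes: Mapping[str, str],
    focal_class: str,
    mode: str = "union",
) -> MotifNetwork:
    """Build the motif network of one class from an all-pairs score table.

    For each motif ``m`` of the focal class, let ``t(m)`` be its highest
    score against any motif outside the class; an edge ``(m, n)`` is
    proposed for every same-class ``n`` with ``score(m, n) > t(m)``
    (strict inequality).  ``mode="union"`` keeps edges proposed from
    either endpoint, ``"intersection"`` only those proposed from both.

    Raises
    ------
    ValueError
        If the focal class has no motifs, or no non-class motifs exist
        (the threshold would be undefined).
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown edge mode {mode!r}")
    members = sorted(m for m, c in classes.items() if c == focal_class)
    if not members:
        raise ValueError(f"no motifs with class {focal_class!r}")
    outsiders = sorted(m for m, c in classes.items() if c != focal_class)
    if not outsiders:
        raise ValueError(
            f"class {focal_class!r}: no non-class motifs to define the "
            "edge threshold"
        )
    missing = [m for m in list(members) + outsiders if m not in scores.index]
    if missing:
        raise ValueError(f"score matrix lacks motifs: {missing}")

    directed: Set[Tuple[str, str]] = set()
    for m in members:
        t = scores.loc[m, outsiders].max()
        for n in members:
            if n != m and scores.loc[m, n] > t:
                directed.add((m, n))
    g = nx.Graph()
    g.add_nodes_from(members)
    for m, n in directed:
        if mode == "union" or (n, m) in directed:
            g.add_edge(*sorted((m, n)))
    return MotifNetwork(
        class_label=focal_class,
        graph=g,
        below_analysis_threshold=len(members) < MIN_CLASS_SIZE,
    )


def mcl(
    network: MotifNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    self_loops: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> NetworkClustering:
    """Markov clustering of a motif network.

    Defaults mirror the canonical MCL program: inflation 2.0, expansion
    power 2, self-loop weight 1.  Deterministic; disconnected nodes end
    up as singletons.
    """
    nodes = network.nodes
    if not nodes:
        raise ValueError("empty network")
    n = len(nodes)
    A = nx.to_numpy_array(network.graph, nodelist=nodes, dtype=float)
    A = A + self_loops * np.eye(n)
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        M2 = np.linalg.matrix_power(M, expansion)
        M2 = np.power(M2, inflation)
        M2 /= M2.sum(axis=0, keepdims=True)
        M2[M2 < 1e-12] = 0.0
        M2 /= M2.sum(axis=0, keepdims=True)
        if np.abs(M2 - M).max() < tol:
            M = M2
            converged = True
            break
        M = M2
    if not converged:
        warnings.warn("MCL did not converge; interpreting current matrix", stacklevel=2)
    clusters = _interpret(M, nodes)
    return NetworkClustering(clusters=clusters, inflation=inflation, converged=converged)


def _interpret(M: np.ndarray, nodes: List[str]) -> List[Set[str]]:
    """Read clusters off attractor rows, merging overlapping systems."""
    n = len(nodes)
    tau = 1e-6
    attractors = [i for i in range(n) if M[i, i] > tau]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    assigned = np.zeros(n, dtype=bool)
    for i in attractors:
        assigned[i] = True
        for j in range(n):
            if M[i, j] > tau:
                union(j, i)
                assigned[j] = True
    # nodes without mass on any attractor (numerically possible): singleton
    groups: Dict[int, Set[str]] = {}
    for j in range(n):
        root = find(j) if assigned[j] else j
        groups.setdefault(root, set()).add(nodes[j])
    return sorted(groups.values(), key=lambda s: sorted(s)[0])


def clusters_to_table(clustering: NetworkClustering) -> pd.DataFrame:
    rows = [
        {"cluster_id": i, "motif_id": m}
        for i, cl in enumerate(clustering.clusters)
        for m in sorted(cl)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "motif_id"])


def write_network(network: MotifNetwork, path, format: str = "edgelist") -> None:
    """Export a network as edge-list TSV or GraphML."""
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for a, b in network.edges:
                fh.write(f"{a}\t{b}\n")
    elif format == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}")
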