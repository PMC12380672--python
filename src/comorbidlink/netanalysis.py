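"""Directed gene-network topology, centrality profiling and hub scoring.

A network is a set of gene symbols with signed directed edges (at most
one per ordered pair, no self-loops).  Topology metrics follow the usual
directed-graph conventions: density m/(n(n-1)); average path length and
diameter over reachable ordered pairs only, so weakly connected networks
still yield finite values; the clustering coefficient is computed on the
undirected projection (the triad definition under which small dense
regulatory modules attain high values).

Centralities: in/out-degree normalized by (n-1), betweenness on directed
shortest paths normalized by (n-1)(n-2), and eigenvector centrality on
the undirected projection by power iteration with max-norm 1.  Hub genes
are ranked by the unweighted mean rank across the four measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedGeneNetwork",
    "NetworkMetrics",
    "CentralityProfile",
    "load_edgelist",
    "write_edgelist",
    "density",
    "path_metrics",
    "clustering_coefficient",
    "centralities",
    "hub_genes",
    "network_metrics",
]

_SIGNS = ("+", "-", "unsigned")


@dataclass(frozen=True)
class DirectedGeneNetwork:
    """Signed directed graph over gene symbols."""

    nodes: frozenset[str]
    edges: tuple[tuple[str, str, str], ...]  # (source, target, sign)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "DirectedGeneNetwork":
        seen: dict[tuple[str, str], str] = {}
        for e in edges:
            src, tgt = e[0], e[1]
            sign = e[2] if len(e) > 2 else "unsigned"
            if sign not in _SIGNS:
                raise ValueError(f"edge sign must be one of {_SIGNS}, got {sign!r}")
            if src == tgt:
                raise ValueError(f"self-loop on {src!r}")
            if (src, tgt) in seen:
                logger.warning("duplicate edge %s -> %s collapsed", src, tgt)
            seen[(src, tgt)] = sign
        nodes = frozenset(extra_nodes) | {n for pair in seen for n in pair}
        return cls(
            nodes=nodes,
            edges=tuple(sorted((s, t, g) for (s, t), g in seen.items())),
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from((s, t, {"sign": sign}) for s, t, sign in self.edges)
        return g


@dataclass(frozen=True)
class NetworkMetrics:
    density: float
    average_path_length: float
    clustering_coefficient: float
    diameter: int
    connected_component_count: int


@dataclass(frozen=True)
class CentralityProfile:
    """Per-node normalized centralities, all in [0, 1]."""

    in_degree: dict[str, float]
    out_degree: dict[str, float]
    betweenness: dict[str, float]
    eigenvector: dict[str, float]
    composite_rank: dict[str, float] = field(default_factory=dict)


def load_edgelist(path: str | Path) -> DirectedGeneNetwork:
    """Read a TSV edge list (source, target[, sign]).

    Self-loop rows are rejected and logged; duplicate ordered pairs are
    collapsed with a warning (last sign wins).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"source", "target"} <= set(frame.columns):
        raise ValueError(f"edge list must have 'source' and 'target' columns: {path}")
    has_sign = "sign" in frame.columns
    edges = []
    for idx, row in frame.iterrows():
        src, tgt = str(row["source"]).strip(), str(row["target"]).strip()
        if src == tgt:
            logger.warning("line %d rejected: self-loop on %r", int(idx) + 2, src)
            continue
        sign = str(row["sign"]).strip() if has_sign else "unsigned"
        edges.append((src, tgt, sign if sign in _SIGNS else "unsigned"))
    return DirectedGeneNetwork.from_edges(edges)


def write_edgelist(net: DirectedGeneNetwork, path: str | Path) -> None:
    pd.DataFrame(net.edges, columns=["source", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def density(net: DirectedGeneNetwork) -> float:
    """Directed density m / (n(n-1))."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return net.n_edges / (n * (n - 1))


def path_metrics(net: DirectedGeneNetwork) -> tuple[float, int]:
    """(average shortest path length, diameter) over reachable ordered pairs."""
    g = net.to_networkx()
    lengths = [
        dist
        for src, targets in nx.all_pairs_shortest_path_length(g)
        for tgt, dist in targets.items()
        if src != tgt
    ]
    if not lengths:
        raise ValueError("no reachable ordered pairs")
    return float(np.mean(lengths)), int(max(lengths))


def clustering_coefficient(net: DirectedGeneNetwork) -> float:
    """Average local clustering on the undirected projection.

    Nodes with undirected degree < 2 contribute 0 to the average.
    """
    if net.n_nodes < 3:
        raise ValueError("clustering requires at least 3 nodes")
    return float(nx.average_clustering(net.to_networkx().to_undirected()))


def _eigenvector_maxnorm(
    g: nx.Graph,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.0,
) -> dict[str, float]:
    """Principal eigenvector of the undirected adjacency by power iteration,
    scaled to max-norm 1.

    Iterates on A + I: the spectral shift leaves the dominant eigenvector
    unchanged but breaks the +/-lambda degeneracy of bipartite projections
    that would otherwise make plain power iteration oscillate.  ``damping``
    additionally mixes in a uniform teleport term.
    """
    nodes = sorted(g.nodes)
    adj = nx.to_numpy_array(g, nodelist=nodes)
    n = len(nodes)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = adj @ x + x
        if damping > 0:
            x_new = (1 - damping) * x_new + damping * np.full(n, x.sum() / n)
        norm = np.max(np.abs(x_new))
        if norm == 0:
            raise ValueError("eigenvector centrality undefined: empty projection")
        x_new = x_new / norm
        if np.max(np.abs(x_new - x)) < tol:
            return dict(zip(nodes, (float(v) for v in x_new)))
        x = x_new
    raise ValueError(
        "eigenvector power iteration did not converge in "
        f"{max_iter} iterations; try damping > 0"
    )


def centralities(net: DirectedGeneNetwork, damping: float = 0.0) -> CentralityProfile:
    """In/out-degree, betweenness and eigenvector centralities, normalized.

    Degree centralities are degree/(n-1); betweenness uses directed
    shortest paths with the standard (n-1)(n-2) normalization; eigenvector
    centrality is computed on the undirected projection with max-norm 1.
    """
    if net.n_nodes < 2:
        raise ValueError("centralities require at least 2 nodes")
    g = net.to_networkx()
    return CentralityProfile(
        in_degree=dict(nx.in_degree_centrality(g)),
        out_degree=dict(nx.out_degree_centrality(g)),
        betweenness=dict(nx.betweenness_centrality(g, normalized=True)),
        eigenvector=_eigenvector_maxnorm(g.to_undirected(), damping=damping),
    )


def hub_genes(profile: CentralityProfile, k: int = 4) -> list[str]:
    """Top-k genes by unweighted mean rank across the four centralities.

    Rank 1 = highest value; ties share the mean rank; the final ordering
    breaks composite ties lexicographically.
    """
    nodes = sorted(profile.in_degree)
    if k > len(nodes):
        raise ValueError(f"k={k} exceeds node count {len(nodes)}")
    ranks = np.zeros(len(nodes))
    for metric in (
        profile.in_degree,
        profile.out_degree,
        profile.betweenness,
        profile.eigenvector,
    ):
        values = np.array([metric[n] for n in nodes])
        ranks += rankdata(-values, method="average")
    composite = ranks / 4.0
    order = sorted(zip(composite, nodes))
    return [name for _, name in order[:k]]


def composite_ranks(profile: CentralityProfile) -> dict[str, float]:
    """Mean rank per node across the four centralities (1 = most central)."""
    nodes = sorted(profile.in_degree)
    ranks = np.zeros(len(nodes))
    for metric in (
        profile.in_degree,
        profile.out_degree,
        profile.betweenness,
        profile.eigenvector,
    ):
        values = np.array([metric[n] for n in nodes])
        ranks += rankdata(-values, method="average")
    return dict(zip(nodes, (float(r) for r in ranks / 4.0)))


def network_metrics(net: DirectedGeneNetwork) -> NetworkMetrics:
    """All topology metrics in one report."""
    apl, diam = path_metrics(net)
    g = net.to_networkx()
    return NetworkMetrics(
        density=density(net),
        average_path_length=apl,
        clustering_coefficient=clustering_coefficient(net),
        diameter=diam,
        connected_component_count=nx.number_weakly_connected_components(g),
    )
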