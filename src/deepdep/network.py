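"""Directed regulatory networks: loading, traversal, and negative-control transforms.

A regulatory network is a directed graph whose nodes are gene identifiers
(opaque, case-sensitive strings) and whose edges run regulator -> target.
Edges optionally carry a regulation sign (``activation``/``inhibition``) and a
dimensionless weight (a correlation in [-1, 1] or a conditional probability in
[0, 1]).  Undirected coexpression edge lists (e.g. ARACNe output awaiting
orientation) are carried by the same class with ``directed=False``.

Two negative-control constructions are provided: node shuffling (a random
relabelling that preserves the graph structure exactly) and edge inversion
(every link reversed), used to show that dependency predictions collapse when
the regulator->target relationships are scrambled or reversed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

SIGNS = ("activation", "inhibition", "unsigned")


@dataclass
class RegulatoryNetwork:
    """A (possibly signed/weighted) gene regulatory graph.

    Parameters
    ----------
    graph
        ``networkx.DiGraph`` for directed networks, ``networkx.Graph`` for
        unoriented coexpression networks.  Edge attributes: ``sign`` (one of
        ``activation``/``inhibition``/``unsigned``) and ``weight`` (float or
        ``None``).
    directed
        Whether edges carry regulator -> target directionality.
    """

    graph: nx.Graph
    directed: bool = True
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        if self.directed and not self.graph.is_directed():
            raise ValueError("directed network requires a DiGraph")
        if not self.directed and self.graph.is_directed():
            raise ValueError("undirected network requires a Graph")
        for u, v, data in self.graph.edges(data=True):
            sign = data.get("sign", "unsigned")
            if sign not in SIGNS:
                raise ValueError(f"invalid sign {sign!r} on edge {u}->{v}")
            w = data.get("weight")
            if w is not None and not (-1.0 - 1e-12 <= float(w) <= 1.0 + 1e-12):
                raise ValueError(f"weight {w} on edge {u}->{v} outside [-1, 1]")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str, dict]]:
        return self.graph.edges(data=True)

    def degree_sequence(self) -> list[int]:
        return sorted(d for _, d in self.graph.degree())


def _parse_row(parts: list[str], lineno: int) -> tuple[str, str, str, Optional[float]]:
    if len(parts) < 2:
        raise ValueError(f"line {lineno}: expected >= 2 columns, got {len(parts)}")
    u, v = parts[0], parts[1]
    sign = "unsigned"
    weight: Optional[float] = None
    for extra in parts[2:4]:
        if extra == "":
            continue
        if extra in SIGNS:
            sign = extra
        else:
            try:
                weight = float(extra)
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: column {extra!r} is neither a sign nor a weight"
                ) from exc
    return u, v, sign, weight


def from_edges(
    edges: Iterable[tuple],
    directed: bool = True,
    extra_nodes: Iterable[str] = (),
) -> RegulatoryNetwork:
    """Build a network from (regulator, target[, sign[, weight]]) tuples.

    Self-loops are dropped with a logged warning; duplicate (regulator,
    target) pairs keep the first occurrence.
    """
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    n_self, n_dup = 0, 0
    for edge in edges:
        u, v = edge[0], edge[1]
        sign = edge[2] if len(edge) > 2 else "unsigned"
        weight = edge[3] if len(edge) > 3 else None
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v, sign=sign, weight=weight)
    g.add_nodes_from(extra_nodes)
    if n_self:
        logger.warning("dropped %d self-loop edge(s)", n_self)
    if n_dup:
        logger.warning("dropped %d duplicate edge(s)", n_dup)
    return RegulatoryNetwork(
        g, directed=directed, n_self_loops_dropped=n_self, n_duplicates_dropped=n_dup
    )


def load_network(path: str | Path, dialect: str = "directed_edges") -> RegulatoryNetwork:
    """Load an edge-list TSV (regulator, target, [sign], [weight]).

    ``#``-prefixed lines are comments.  ``dialect`` is ``directed_edges`` or
    ``undirected_edges``; the undirected dialect stores each pair once and the
    resulting network is flagged unoriented.
    """
    if dialect not in ("directed_edges", "undirected_edges"):
        raise ValueError(f"unknown dialect {dialect!r}")
    edges = []
    first_data_row = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if first_data_row:
                first_data_row = False
                if parts[0].lower() in ("regulator", "source", "gene1"):
                    continue  # header row
            edges.append(_parse_row(parts, lineno))
    return from_edges(edges, directed=(dialect == "directed_edges"))


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write the edge list as TSV with sign and weight columns."""
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tsign\tweight\n")
        for u, v, data in sorted(net.edges()):
            w = data.get("weight")
            fh.write(f"{u}\t{v}\t{data.get('sign', 'unsigned')}\t{'' if w is None else w}\n")


def descendants(net: RegulatoryNetwork, gene: str) -> set[str]:
    """All genes reachable from ``gene`` via outgoing links, excluding itself.

    Only reachability matters; the structure of intervening nodes is ignored.
    A gene reachable from itself through a cycle is still excluded (its own
    level is set directly by the perturbation rule).
    """
    if not net.directed:
        raise ValueError("descendants requires a directed network")
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} not in network")
    return nx.descendants(net.graph, gene) - {gene}


def ancestors(net: RegulatoryNetwork, gene: str) -> set[str]:
    """All genes from which ``gene`` is reachable, excluding itself."""
    if not net.directed:
        raise ValueError("ancestors requires a directed network")
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} not in network")
    return nx.ancestors(net.graph, gene) - {gene}


def regulatory_targets(net: RegulatoryNetwork, gene: str) -> set[str]:
    """Direct (one-hop) regulatory targets of ``gene``."""
    if not net.directed:
        raise ValueError("regulatory_targets requires a directed network")
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} not in network")
    return set(net.graph.successors(gene))


def shuffle_nodes(net: RegulatoryNetwork, seed: int) -> RegulatoryNetwork:
    """Negative control: random node relabelling preserving network structure.

    Node labels are permuted jointly; each edge's sign and weight stay attached
    to the edge, so the shuffled graph is isomorphic to the original.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(net.graph.nodes)
    permuted = [nodes[i] for i in rng.permutation(len(nodes))]
    mapping = dict(zip(nodes, permuted))
    g = nx.relabel_nodes(net.graph, mapping, copy=True)
    return RegulatoryNetwork(g, directed=net.directed)


def invert(net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Negative control: reverse the direction of every link."""
    if not net.directed:
        raise ValueError("cannot invert an unoriented network")
    return RegulatoryNetwork(net.graph.reverse(copy=True), directed=True)


def eligible_targets(
    net: RegulatoryNetwork,
    sample_genes: set[str],
    min_downstream: int = 1,
    count: str = "descendants",
) -> set[str]:
    """Genes eligible for in silico perturbation.

    A gene qualifies when it has at least ``min_downstream`` downstream genes
    (all ``descendants``, or direct regulatory ``targets`` for an oriented
    coexpression network) and its expression is available in ``sample_genes``.
    Terminal nodes never qualify.
    """
    if count not in ("descendants", "targets"):
        raise ValueError(f"unknown count mode {count!r}")
    out = set()
    for gene in net.graph.nodes:
        if gene not in sample_genes:
            continue
        if count == "descendants":
            n_down = len(descendants(net, gene))
        else:
            n_down = len(regulatory_targets(net, gene))
        if n_down >= min_downstream:
            out.add(gene)
    return out
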