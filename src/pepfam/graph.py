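"""Similarity-graph construction and pruning.

The pipeline turns directed SRV hits into an undirected weighted graph and
then thins it in four stages: threshold filtering at graph build, single-pass
removal of singletons and pendant nodes, mutual k-best edge retention at the
minimal non-isolating k, and a per-component edge-weight threshold prune.
Components of the final graph are batched by mean degree and mean edge weight
so that the Markov-clustering inflation can be tuned per batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .similarity import SrvHit

DEFAULT_MIN_SRV = 0.3
DEFAULT_MIN_COVERAGE = 0.70


def build_graph(
    hits: Iterable[SrvHit],
    universe: Iterable[str] | None = None,
    min_srv: float = DEFAULT_MIN_SRV,
    min_cov: float = DEFAULT_MIN_COVERAGE,
    require_reciprocal: bool = False,
) -> nx.Graph:
    """Filter directed hits and average reciprocal SRVs into an undirected graph.

    A directed hit survives iff ``srv >= min_srv`` and both coverages are
    ``>= min_cov`` (mutual coverage).  Surviving reciprocal pairs are averaged
    into one edge weight; a surviving one-directional hit contributes its own
    SRV unless ``require_reciprocal`` is set, in which case it is dropped.
    Nodes include every id in ``universe`` (default: ids appearing in hits),
    so proteins without surviving homologs stay visible as isolated nodes.
    """
    surviving: dict[tuple[str, str], float] = {}
    seen_ids: set[str] = set()
    for h in hits:
        seen_ids.update((h.query_id, h.subject_id))
        if h.srv >= min_srv and h.q_coverage >= min_cov and h.s_coverage >= min_cov:
            surviving[(h.query_id, h.subject_id)] = h.srv
    g = nx.Graph()
    g.add_nodes_from(sorted(universe) if universe is not None else sorted(seen_ids))
    for (q, s), srv in sorted(surviving.items()):
        if (s, q) in surviving:
            if q < s:  # add each reciprocal pair once
                g.add_edge(q, s, weight=(srv + surviving[(s, q)]) / 2.0)
        elif not require_reciprocal:
            g.add_edge(q, s, weight=srv)
    return g


@dataclass
class PruneReport:
    """Ids removed before clustering, kept for the singleton statistics."""

    singletons: list[str] = field(default_factory=list)
    pendants: list[str] = field(default_factory=list)


def drop_singletons_and_pendants(g: nx.Graph) -> tuple[nx.Graph, PruneReport]:
    """Remove degree-0 and degree-1 nodes in one simultaneous pass.

    Degrees are taken on the input graph, not recomputed as nodes fall away,
    so a chain interior that loses both neighbours survives (with degree 0)
    rather than being peeled iteratively.
    """
    report = PruneReport(
        singletons=sorted(n for n in g if g.degree(n) == 0),
        pendants=sorted(n for n in g if g.degree(n) == 1),
    )
    keep = [n for n in g if g.degree(n) >= 2]
    return g.subgraph(keep).copy(), report


def _top_k_neighbors(g: nx.Graph, node: str, k: int) -> set[str]:
    # heaviest first; ties by ascending neighbour id
    ranked = sorted(g[node].items(), key=lambda kv: (-kv[1]["weight"], kv[0]))
    return {nbr for nbr, _ in ranked[:k]}


def prune_k_best(g: nx.Graph, k: int) -> nx.Graph:
    """Mutual k-best retention: an edge survives iff it ranks in the top-k
    lists of *both* endpoints.  Node set unchanged."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tops = {n: _top_k_neighbors(g, n, k) for n in g}
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    for a, b, data in g.edges(data=True):
        if b in tops[a] and a in tops[b]:
            out.add_edge(a, b, weight=data["weight"])
    return out


def select_k(g: nx.Graph) -> int:
    """Smallest k >= 1 for which mutual k-best pruning isolates no node."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = dict(g.degree())
    if min(degrees.values()) == 0:
        raise ValueError("graph already contains a degree-0 node")
    max_degree = max(degrees.values())
    for k in range(1, max_degree + 1):
        pruned = prune_k_best(g, k)
        if min(dict(pruned.degree()).values()) >= 1:
            return k
    return max_degree  # k = max degree keeps every edge; unreachable fallback


@dataclass
class Component:
    """A connected subgraph with its batching statistics."""

    graph: nx.Graph
    mean_degree: float
    mean_edge_weight: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edge_mass(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


def _make_component(sub: nx.Graph) -> Component:
    n, e = sub.number_of_nodes(), sub.number_of_edges()
    weights = [d["weight"] for _, _, d in sub.edges(data=True)]
    return Component(
        graph=sub,
        mean_degree=2.0 * e / n if n else 0.0,
        mean_edge_weight=float(np.mean(weights)) if weights else 0.0,
    )


def split_components(g: nx.Graph) -> list[Component]:
    """Maximal connected subgraphs, ordered by (size desc, smallest id asc)."""
    comps = [_make_component(g.subgraph(c).copy()) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-c.graph.number_of_nodes(), min(c.graph.nodes)))
    return comps


def component_threshold_prune(component: Component) -> Component:
    """Per-component weak-edge removal.

    Among the component's distinct edge weights, pick the largest threshold t
    such that dropping every edge with weight < t isolates no node, then drop
    those edges.  The component may split afterwards — splitting likely
    separates clusters that the weak edges were bridging, which is the point.
    """
    g = component.graph
    weights = sorted({d["weight"] for _, _, d in g.edges(data=True)})
    chosen = None
    for t in weights:
        pruned_degree = {n: 0 for n in g}
        for a, b, d in g.edges(data=True):
            if d["weight"] >= t:
                pruned_degree[a] += 1
                pruned_degree[b] += 1
        if min(pruned_degree.values()) >= 1:
            chosen = t
    if chosen is None:
        return component
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    for a, b, d in g.edges(data=True):
        if d["weight"] >= chosen:
            out.add_edge(a, b, weight=d["weight"])
    return _make_component(out)


@dataclass
class Batch:
    """Components sharing a (mean-degree, mean-weight) quantile-grid cell."""

    components: list[Component]
    degree_bin: int
    weight_bin: int


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value a quantile bin; degenerate distributions collapse."""
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, values, side="left")


def batch_components(
    components: Sequence[Component], degree_bins: int = 4, weight_bins: int = 4
) -> list[Batch]:
    """Partition components into a quantile grid over their two statistics."""
    if not components:
        raise ValueError("batch_components requires at least one component")
    deg = np.array([c.mean_degree for c in components])
    wt = np.array([c.mean_edge_weight for c in components])
    dbin = _quantile_bins(deg, degree_bins)
    wbin = _quantile_bins(wt, weight_bins)
    cells: dict[tuple[int, int], list[Component]] = {}
    for c, db, wb in zip(components, dbin, wbin):
        cells.setdefault((int(db), int(wb)), []).append(c)
    return [
        Batch(components=cells[key], degree_bin=key[0], weight_bin=key[1])
        for key in sorted(cells)
    ]
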