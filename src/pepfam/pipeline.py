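"""End-to-end family discovery: proteins in, families and a partition out.

Stages: all-against-all local alignment with SRV computation; threshold
filtering and reciprocal averaging into an undirected graph; single-pass
singleton/pendant exclusion; mutual k-best pruning at the minimal
non-isolating k; per-component weak-edge pruning; batching of components by
mean degree and mean edge weight; per-batch Markov clustering with inflation
selection; family calling at five or more members with alignment, profile,
gathering cutoff and product vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import graph as graphmod
from .families import (
    DEFAULT_MIN_FAMILY_SIZE,
    Family,
    FamilyCallReport,
    build_families,
    call_families,
)
from .io import ProteinRecord
from .mcl import DEFAULT_INFLATION_GRID, Clustering, SweepResult, inflation_sweep
from .scoring import ScoringScheme
from .similarity import DEFAULT_EVALUE_CEILING, SrvHit, all_vs_all

MAX_CLUSTERING_LENGTH = 50


@dataclass(frozen=True)
class PipelineConfig:
    min_srv: float = graphmod.DEFAULT_MIN_SRV
    min_cov: float = graphmod.DEFAULT_MIN_COVERAGE
    e_value_ceiling: float = DEFAULT_EVALUE_CEILING
    require_reciprocal: bool = False
    k: int | None = None  # None => minimal non-isolating k
    degree_bins: int = 4
    weight_bins: int = 4
    inflation_grid: tuple[float, ...] = DEFAULT_INFLATION_GRID
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE
    max_length: int = MAX_CLUSTERING_LENGTH


@dataclass
class PipelineResult:
    hits: list[SrvHit]
    clustered: Clustering  # partition of the nodes that reached MCL
    families: list[Family]
    call_report: FamilyCallReport
    excluded: dict[str, str]  # id -> reason for exclusion before MCL
    chosen_inflations: list[float] = field(default_factory=list)
    selected_k: int | None = None

    def full_partition(self) -> Clustering:
        """Partition of every input id; excluded ids become singleton clusters."""
        assignment = dict(self.clustered.assignment)
        next_id = max(assignment.values(), default=-1) + 1
        for pid in sorted(self.excluded):
            assignment[pid] = next_id
            next_id += 1
        return Clustering(assignment=assignment)


def run_pipeline(
    proteins: Sequence[ProteinRecord],
    scheme: ScoringScheme | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full family-discovery pipeline on small proteins (<= 50 aa)."""
    scheme = scheme or ScoringScheme()
    config = config or PipelineConfig()
    too_long = [p.id for p in proteins if len(p.sequence) > config.max_length]
    if too_long:
        raise ValueError(
            f"clustering input must be <= {config.max_length} aa; offending ids: {too_long[:5]}"
        )
    ids = [p.id for p in proteins]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate protein ids in input")

    excluded: dict[str, str] = {}
    hits = all_vs_all(proteins, scheme, e_value_ceiling=config.e_value_ceiling)
    g = graphmod.build_graph(
        hits,
        universe=ids,
        min_srv=config.min_srv,
        min_cov=config.min_cov,
        require_reciprocal=config.require_reciprocal,
    )
    g, report = graphmod.drop_singletons_and_pendants(g)
    for pid in report.singletons:
        excluded[pid] = "singleton"
    for pid in report.pendants:
        excluded[pid] = "pendant"
    # nodes that lost all edges in the pendant pass join the singleton report
    isolated = sorted(n for n in g if g.degree(n) == 0)
    for pid in isolated:
        excluded[pid] = "isolated-after-pruning"
    g = g.subgraph([n for n in g if g.degree(n) >= 1]).copy()

    if g.number_of_nodes() == 0:
        empty = Clustering(assignment={})
        return PipelineResult(
            hits=hits,
            clustered=empty,
            families=[],
            call_report=call_families(empty, config.min_family_size),
            excluded=excluded,
        )

    k = config.k if config.k is not None else graphmod.select_k(g)
    g = graphmod.prune_k_best(g, k)
    components = graphmod.split_components(g)
    pruned = [graphmod.component_threshold_prune(c) for c in components]
    # threshold pruning may split components; re-split before batching
    final_components = []
    for comp in pruned:
        final_components.extend(graphmod.split_components(comp.graph))
    final_components.sort(key=lambda c: (-c.graph.number_of_nodes(), min(c.graph.nodes)))
    batches = graphmod.batch_components(
        final_components, degree_bins=config.degree_bins, weight_bins=config.weight_bins
    )

    assignment: dict[str, int] = {}
    next_cluster = 0
    inflations: list[float] = []
    for batch in batches:
        sweep: SweepResult = inflation_sweep(batch, config.inflation_grid)
        inflations.append(sweep.inflation)
        for clustering in sweep.clusterings:
            for cluster in clustering.clusters():
                for node in cluster:
                    assignment[node] = next_cluster
                next_cluster += 1
    clustered = Clustering(assignment=assignment)

    call_report = call_families(clustered, config.min_family_size)
    records_by_id = {p.id: p for p in proteins}
    families = build_families(call_report.families, records_by_id, scheme)
    return PipelineResult(
        hits=hits,
        clustered=clustered,
        families=families,
        call_report=call_report,
        excluded=excluded,
        chosen_inflations=inflations,
        selected_k=k,
    )
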