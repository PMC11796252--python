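"""SRV (score ratio value) computation and homology screening.

The SRV of a directed hit is its alignment bit score divided by the query's
self-alignment bit score ("observed score over maximum score").  Being a
ratio, it stays comparable across the very short sequences where absolute
bit-score or E-value thresholds become length-biased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import HitTableRow, ProteinRecord
from .scoring import ScoringScheme, local_align, self_raw_score

#: Hits with a larger E-value proxy than this are discarded before any SRV logic.
DEFAULT_EVALUE_CEILING = 1e-5

#: Tolerated numeric excess of table-derived SRVs above 1 (rounding only).
_SRV_SLACK = 1e-6


class SrvInconsistencyError(ValueError):
    """An observed bit score exceeds the query self score by more than rounding."""


@dataclass(frozen=True)
class SrvHit:
    """One directed hit with its SRV and both-sided alignment coverage."""

    query_id: str
    subject_id: str
    bit_score: float
    srv: float
    q_coverage: float
    s_coverage: float
    e_value: float


def self_scores(proteins: Iterable[ProteinRecord], scheme: ScoringScheme) -> dict[str, float]:
    """Self-alignment bit score per protein (the SRV denominator)."""
    return {p.id: scheme.raw_to_bits(self_raw_score(p.sequence, scheme)) for p in proteins}


def compute_srv(hit: HitTableRow, self_scores: Mapping[str, float]) -> float:
    """SRV = hit bit score / query self bit score, clamped at 1 within rounding."""
    denom = self_scores[hit.query_id]
    srv = hit.bit_score / denom
    if srv > 1.0 + _SRV_SLACK:
        raise SrvInconsistencyError(
            f"hit {hit.query_id}->{hit.subject_id}: bit score {hit.bit_score} exceeds "
            f"query self score {denom}"
        )
    return min(srv, 1.0)


def srv_hits_from_rows(
    rows: Iterable[HitTableRow],
    self_scores: Mapping[str, float],
    e_value_ceiling: float = DEFAULT_EVALUE_CEILING,
) -> list[SrvHit]:
    """Convert hit-table rows (lengths filled) to SRV hits, E-value gated.

    Self-hits (query == subject) are dropped: they define the denominator,
    not an edge.
    """
    out = []
    for row in rows:
        if row.query_id == row.subject_id:
            continue
        if row.e_value > e_value_ceiling:
            continue
        out.append(
            SrvHit(
                query_id=row.query_id,
                subject_id=row.subject_id,
                bit_score=row.bit_score,
                srv=compute_srv(row, self_scores),
                q_coverage=row.q_coverage,
                s_coverage=row.s_coverage,
                e_value=row.e_value,
            )
        )
    return out


def _mirror(row: HitTableRow) -> HitTableRow:
    return HitTableRow(
        query_id=row.subject_id,
        subject_id=row.query_id,
        percent_identity=row.percent_identity,
        alignment_length=row.alignment_length,
        mismatches=row.mismatches,
        gap_opens=row.gap_opens,
        q_start=row.s_start,
        q_end=row.s_end,
        s_start=row.q_start,
        s_end=row.q_end,
        e_value=row.e_value,
        bit_score=row.bit_score,
        q_len=row.s_len,
        s_len=row.q_len,
    )


def all_vs_all(
    proteins: Sequence[ProteinRecord],
    scheme: ScoringScheme,
    e_value_ceiling: float = DEFAULT_EVALUE_CEILING,
) -> list[SrvHit]:
    """All-against-all local alignment, one optimal hit per ordered pair.

    Each unordered pair is aligned once; the reverse direction reuses the
    same (symmetric-score) alignment with coordinates swapped.  Hits whose
    E-value proxy exceeds the ceiling are dropped before SRV thresholds are
    ever considered.  Zero-score pairs (no positive-scoring path) produce no
    hit.
    """
    if len(proteins) < 2:
        raise ValueError("all_vs_all needs at least two proteins")
    selfs = self_scores(proteins, scheme)
    hits: list[SrvHit] = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            row = local_align(a, b, scheme)
            if row.alignment_length == 0:
                continue
            for directed in (row, _mirror(row)):
                if directed.e_value > e_value_ceiling:
                    continue
                hits.append(
                    SrvHit(
                        query_id=directed.query_id,
                        subject_id=directed.subject_id,
                        bit_score=directed.bit_score,
                        srv=compute_srv(directed, selfs),
                        q_coverage=directed.q_coverage,
                        s_coverage=directed.s_coverage,
                        e_value=directed.e_value,
                    )
                )
    return hits


def homology_screen(
    queries: Sequence[ProteinRecord],
    references: Sequence[ProteinRecord],
    scheme: ScoringScheme,
    min_srv: float = 0.7,
    e_value_ceiling: float = DEFAULT_EVALUE_CEILING,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Keep queries with a reference homolog at SRV >= ``min_srv``.

    Returns the accepted queries (input order) and a re-annotation map:
    accepted queries whose own product is absent or "hypothetical protein"
    inherit the product of their best reference hit (best SRV, ties broken
    by bit score then reference id).
    """
    if not references:
        raise ValueError("homology_screen requires a non-empty reference set")
    selfs = self_scores(queries, scheme)
    accepted: list[ProteinRecord] = []
    reannotation: dict[str, str] = {}
    for q in queries:
        best: tuple[float, float, str] | None = None  # (srv, bit, ref_id) maximised
        best_ref: ProteinRecord | None = None
        for ref in references:
            row = local_align(q, ref, scheme)
            if row.alignment_length == 0 or row.e_value > e_value_ceiling:
                continue
            srv = compute_srv(row, selfs)
            key = (srv, row.bit_score, ref.id)
            # ref id ties break ascending: invert comparison for the id field
            if best is None or (srv, row.bit_score) > (best[0], best[1]) or (
                (srv, row.bit_score) == (best[0], best[1]) and ref.id < best[2]
            ):
                best = key
                best_ref = ref
        if best is not None and best[0] >= min_srv:
            accepted.append(q)
            uninformative = q.product is None or q.product.strip().lower() == "hypothetical protein"
            if uninformative and best_ref is not None and best_ref.product:
                reannotation[q.id] = best_ref.product
    return accepted, reannotation
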