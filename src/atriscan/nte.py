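"""Screen for unique N-terminal extensions (NTEs).

A protein carries an NTE when every retained homolog alignment begins
strictly downstream of its N-terminus: the residues before the earliest
aligned query position are present in the query but in none of its
homologs. The screen filters homolog hits (similarity > 30%, query
coverage > 70%, strict inequalities), caps them at the top 250 by rank
score, and measures the unaligned N-terminal overhang.

"Unique" is operationalized over per-hit overhangs: for one hit the
overhang is the number of query residues preceding the position
homologous to the subject's residue 1, i.e. ``query_start -
subject_start`` (falling back to ``query_start - 1`` when the subject
start is unknown — the two coincide whenever the alignment reaches the
subject's own N-terminus). The call takes the minimum overhang over all
retained hits, so a single homolog whose N-terminus maps to the query
N-terminus vetoes the call; a quantile option relaxes this to a
majority-style rule. Subtracting the subject start keeps the
measurement exact when a boundary mismatch makes the local alignment
trim its first column on both sequences at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .amphipathic import AmphipathicityResult
from .seq_io import HomologHit, ProteinRecord


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds of the NTE screen.

    ``min_similarity_pct`` / ``min_coverage_pct`` are strict
    lower bounds (a hit at exactly 30% similarity is excluded).
    ``min_support`` guards against calling uniqueness from too few
    informative homologs; ``start_quantile`` = 0 uses the minimum
    retained query start (strict uniqueness), larger values tolerate a
    fraction of N-terminus-covering hits. ``max_nte_len`` only flags
    out-of-range calls, it does not suppress them.
    """

    min_similarity_pct: float = 30.0
    min_coverage_pct: float = 70.0
    top_k: int = 250
    min_nte_len: int = 10
    max_nte_len: int | None = None
    min_support: int = 10
    start_quantile: float = 0.0
    check_subject_start: bool = True
    max_subject_start_offset: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.min_similarity_pct <= 100 and 0 <= self.min_coverage_pct <= 100):
            raise ValueError("thresholds must lie in [0, 100]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_nte_len < 1:
            raise ValueError("min_nte_len must be >= 1")
        if not 0.0 <= self.start_quantile < 1.0:
            raise ValueError("start_quantile must lie in [0, 1)")


@dataclass(frozen=True)
class NteCall:
    """Per-protein screen verdict."""

    query_id: str
    query_length: int
    n_hits_retained: int
    min_query_start: int | None
    nte_length: int
    is_nte: bool
    status: str = "ok"
    conserved_in: tuple[str, ...] = ()
    amphipathic: AmphipathicityResult | None = None


def filter_and_rank(hits: Iterable[HomologHit], params: ScreenParams | None = None) -> list[HomologHit]:
    """Apply the similarity/coverage filters and keep the top-k by rank score.

    All hits must share one query id and one score scale (raw in-house
    scores and BLAST bit scores must never be ranked together). Ties in
    rank score are broken by lexicographic subject id.
    """
    params = params or ScreenParams()
    hits = list(hits)
    if not hits:
        return []
    query_ids = {h.query_id for h in hits}
    if len(query_ids) > 1:
        raise ValueError(f"hits mix query ids: {sorted(query_ids)}")
    scales = {h.score_scale for h in hits}
    if len(scales) > 1:
        raise ValueError(
            f"hits mix rank-score scales {sorted(scales)}; in-house and "
            "parsed BLAST hits cannot be ranked together"
        )
    passing = [
        h
        for h in hits
        if h.similarity_pct > params.min_similarity_pct
        and h.coverage_pct > params.min_coverage_pct
    ]
    passing.sort(key=lambda h: (-h.rank_score, h.subject_id))
    return passing[: params.top_k]


def _start_at_quantile(starts: Sequence[int], q: float) -> int:
    """The q-quantile of retained query starts (q=0 -> minimum)."""
    ordered = sorted(starts)
    idx = math.floor(q * (len(ordered) - 1)) if len(ordered) > 1 else 0
    return ordered[idx]


def call_nte(
    query: ProteinRecord, retained: Sequence[HomologHit], params: ScreenParams | None = None
) -> NteCall:
    """Measure the unique N-terminal overhang of one query.

    ``retained`` must already have passed :func:`filter_and_rank`.
    Fewer than ``min_support`` hits yields an ``insufficient-support``
    call (is_nte False), not an error. When subject starts are
    available and ``check_subject_start`` is on, a call is downgraded
    to ``subject-start-uncertain`` unless every retained alignment
    begins within ``max_subject_start_offset`` residues of its
    subject's own N-terminus — guarding against local-alignment
    truncation masquerading as an extension.
    """
    params = params or ScreenParams()
    n = len(retained)
    if n == 0:
        return NteCall(
            query_id=query.protein_id,
            query_length=len(query),
            n_hits_retained=0,
            min_query_start=None,
            nte_length=0,
            is_nte=False,
            status="insufficient-support",
        )
    start = _start_at_quantile([h.query_start for h in retained], params.start_quantile)
    overhangs = [
        max(0, h.query_start - (h.subject_start if h.subject_start is not None else 1))
        for h in retained
    ]
    nte_length = _start_at_quantile(overhangs, params.start_quantile)
    status = "ok"
    is_nte = nte_length >= params.min_nte_len
    if n < params.min_support:
        is_nte = False
        status = "insufficient-support"
    elif is_nte and params.check_subject_start:
        subject_starts = [h.subject_start for h in retained]
        if all(s is not None for s in subject_starts):
            if any(s - 1 > params.max_subject_start_offset for s in subject_starts):
                is_nte = False
                status = "subject-start-uncertain"
    if is_nte and params.max_nte_len is not None and nte_length > params.max_nte_len:
        status = "out-of-range"
    return NteCall(
        query_id=query.protein_id,
        query_length=len(query),
        n_hits_retained=n,
        min_query_start=start,
        nte_length=nte_length,
        is_nte=is_nte,
        status=status,
    )


def conservation_scan(
    calls_by_genome: Mapping[str, Mapping[str, NteCall]],
    ortholog_pairs: Iterable[tuple[str, str, str, str]],
) -> dict[str, dict[str, NteCall]]:
    """Annotate NTE calls with the genomes whose orthologs share the NTE.

    ``ortholog_pairs`` are ``(genome_a, protein_a, genome_b, protein_b)``
    tuples (direction-free). For every positive call, ``conserved_in``
    lists each other genome whose paired ortholog also has a positive
    call.
    """
    partner: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for ga, pa, gb, pb in ortholog_pairs:
        partner.setdefault((ga, pa), set()).add((gb, pb))
        partner.setdefault((gb, pb), set()).add((ga, pa))
    annotated: dict[str, dict[str, NteCall]] = {}
    for genome, calls in calls_by_genome.items():
        annotated[genome] = {}
        for pid, call in calls.items():
            if call.is_nte:
                conserved = sorted(
                    g
                    for g, p in partner.get((genome, pid), ())
                    if g != genome and calls_by_genome.get(g, {}).get(p, None) is not None
                    and calls_by_genome[g][p].is_nte
                )
                call = replace(call, conserved_in=tuple(conserved))
            annotated[genome][pid] = call
    return annotated


def cluster_families(
    hits_by_query: Mapping[str, Sequence[HomologHit]], params: ScreenParams | None = None
) -> dict[str, set[str]]:
    """Single-linkage protein families from within-proteome homolog hits.

    An edge joins query and subject whenever the hit passes the same
    strict similarity/coverage filters used by the screen; families are
    the connected components, keyed ``famNNN`` in order of their
    lexicographically smallest member.
    """
    params = params or ScreenParams()
    graph = nx.Graph()
    for qid, hits in hits_by_query.items():
        graph.add_node(qid)
        for h in filter_and_rank(list(hits), params):
            graph.add_edge(h.query_id, h.subject_id)
    components = sorted(nx.connected_components(graph), key=min)
    return {f"fam{i:03d}": set(comp) for i, comp in enumerate(components)}


def paralog_nte_pairs(
    families: Mapping[str, Iterable[str]], calls: Mapping[str, NteCall]
) -> list[tuple[str, str, str]]:
    """Families carrying both a conventional member and an NTE member.

    Mirrors the dual-FtsZ motif: one paralog with no N-terminal
    overhang (nte_length 0) and one with a positive NTE call. Returns
    ``(conventional_id, nte_id, family_id)`` for every such combination.
    """
    out: list[tuple[str, str, str]] = []
    for fam_id in sorted(families):
        members = sorted(families[fam_id])
        conventional = [
            m for m in members if m in calls and not calls[m].is_nte and calls[m].nte_length == 0
        ]
        with_nte = [m for m in members if m in calls and calls[m].is_nte]
        for c in conventional:
            for n in with_nte:
                out.append((c, n, fam_id))
    return out
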