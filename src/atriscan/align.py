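"""Built-in protein pairwise alignment with BLAST-like hit statistics.

The screen normally consumes BLAST tabular input, but it can also run
self-contained: queries are aligned against a subject database with an
affine-gap dynamic-programming aligner (Biopython's ``PairwiseAligner``,
BLOSUM62, gap open 11 / extend 1 — the BLASTP defaults). The affine
cost follows the BLAST convention: the first residue of a gap costs
``gap_open + gap_extend``, every further residue ``gap_extend``.

In-house hits carry raw alignment scores (``score_scale="raw"``);
parsed BLAST hits carry bit scores. The two scales are incomparable and
:func:`atriscan.nte.filter_and_rank` refuses to rank them together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .seq_io import HomologHit, Proteome

MODES = ("local", "global")


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme of the built-in aligner."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    mode: str = "local"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


@lru_cache(maxsize=8)
def load_matrix(name: str):
    """Load a named NCBI substitution matrix (cached)."""
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal pairwise alignment.

    ``aligned_pairs`` lists alignment columns as 1-based
    ``(query_pos | None, subject_pos | None)`` tuples; ``None`` marks a
    gap. ``positives_pct`` counts columns whose substitution score is
    positive, over all alignment columns (gaps included), matching the
    BLAST "positives" notion of similarity.
    """

    score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_pairs: tuple[tuple[int | None, int | None], ...]
    identity_pct: float
    positives_pct: float
    params: AlignParams = field(default=AlignParams(), compare=False)


def _make_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = load_matrix(params.matrix_name)
    # Biopython's open_gap_score is charged to the first gap residue.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = params.mode
    return aligner


def align(query: str, subject: str, params: AlignParams | None = None) -> AlignmentResult | None:
    """Optimal affine-gap alignment of two protein sequences.

    Returns ``None`` in local mode when no alignment scores above zero
    (reported downstream as "no hit"). Among co-optimal alignments the
    first in Biopython's deterministic traceback order is taken, so
    reruns are reproducible.
    """
    params = params or AlignParams()
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(params)
    alignments = aligner.align(query, subject)
    if params.mode == "local" and alignments.score <= 0:
        return None
    aln = alignments[0]
    matrix = load_matrix(params.matrix_name)

    pairs: list[tuple[int | None, int | None]] = []
    identities = 0
    positives = 0
    q_blocks, s_blocks = aln.aligned
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q is not None:
            for i in range(prev_q, qs):  # deletion in subject
                pairs.append((i + 1, None))
            for j in range(prev_s, ss):  # insertion in subject
                pairs.append((None, j + 1))
        for i, j in zip(range(qs, qe), range(ss, se)):
            pairs.append((i + 1, j + 1))
            a, b = query[i], subject[j]
            if a == b:
                identities += 1
            if matrix[a, b] > 0:
                positives += 1
        prev_q, prev_s = qe, se
    n_cols = len(pairs)
    if n_cols == 0:
        return None
    q_positions = [q for q, _ in pairs if q is not None]
    s_positions = [s for _, s in pairs if s is not None]
    return AlignmentResult(
        score=float(alignments.score),
        query_start=min(q_positions),
        query_end=max(q_positions),
        subject_start=min(s_positions),
        subject_end=max(s_positions),
        aligned_pairs=tuple(pairs),
        identity_pct=identities / n_cols * 100.0,
        positives_pct=positives / n_cols * 100.0,
        params=params,
    )


def rescore(result: AlignmentResult, query: str, subject: str) -> float:
    """Recompute the alignment score column-by-column (consistency check)."""
    params = result.params
    matrix = load_matrix(params.matrix_name)
    score = 0.0
    gap_state = None  # "q" or "s" while inside a gap
    for q, s in result.aligned_pairs:
        if q is not None and s is not None:
            score += matrix[query[q - 1], subject[s - 1]]
            gap_state = None
        else:
            side = "q" if q is None else "s"
            if gap_state == side:
                score -= params.gap_extend
            else:
                score -= params.gap_open + params.gap_extend
            gap_state = side
    return score


def hits_from_alignment(
    result: AlignmentResult, query_id: str, subject_id: str, query_length: int
) -> HomologHit:
    """Convert an alignment into the hit summary the screen consumes."""
    return HomologHit(
        query_id=query_id,
        subject_id=subject_id,
        similarity_pct=result.positives_pct,
        coverage_pct=(result.query_end - result.query_start + 1) / query_length * 100.0,
        query_start=result.query_start,
        query_end=result.query_end,
        rank_score=result.score,
        subject_start=result.subject_start,
        similarity_source="positives",
        score_scale="raw",
    )


def search(
    query_id: str,
    query_seq: str,
    subjects: Proteome,
    params: AlignParams | None = None,
    *,
    skip_self: bool = True,
) -> list[HomologHit]:
    """Align one query against every subject, returning hit summaries."""
    hits = []
    for rec in subjects:
        if skip_self and rec.protein_id == query_id:
            continue
        result = align(query_seq, rec.sequence, params)
        if result is not None:
            hits.append(hits_from_alignment(result, query_id, rec.protein_id, len(query_seq)))
    return hits


def _best_hits(a: Proteome, b: Proteome, params: AlignParams):
    """Best subject in ``b`` for each protein of ``a`` (ties: lexicographic id)."""
    best: dict[str, tuple[float, str]] = {}
    ties: list[str] = []
    for rec in a:
        scored = []
        for sub in b:
            res = align(rec.sequence, sub.sequence, params)
            if res is not None:
                scored.append((res.score, sub.protein_id))
        if not scored:
            continue
        top = max(s for s, _ in scored)
        top_ids = sorted(pid for s, pid in scored if s == top)
        if len(top_ids) > 1:
            ties.append(
                f"{rec.protein_id}: tie at score {top} among {top_ids}; kept {top_ids[0]}"
            )
        best[rec.protein_id] = (top, top_ids[0])
    return best, ties


def reciprocal_best_hits(
    proteome_a: Proteome, proteome_b: Proteome, params: AlignParams | None = None
) -> tuple[list[tuple[str, str]], list[str]]:
    """Reciprocal-best-hit ortholog pairs between two proteomes.

    Returns ``(pairs, warnings)`` where pairs are ``(id_in_a, id_in_b)``
    and warnings describe score ties broken lexicographically.
    """
    params = params or AlignParams()
    fwd, ties_f = _best_hits(proteome_a, proteome_b, params)
    rev, ties_r = _best_hits(proteome_b, proteome_a, params)
    pairs = [
        (a_id, b_id)
        for a_id, (_, b_id) in sorted(fwd.items())
        if b_id in rev and rev[b_id][1] == a_id
    ]
    return pairs, ties_f + ties_r
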