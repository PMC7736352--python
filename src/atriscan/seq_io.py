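"""Readers/writers for the formats the pipeline touches.

Sequence I/O goes through Biopython; the predictor summary dialects
(BLAST tabular, TMHMM-short, two-column signal-peptide summaries) are
parsed line-wise so that malformed input can be reported with a line
number. All coordinates are 1-based closed intervals, matching the
BLAST/TMHMM convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 canonical residues plus the ambiguity code X
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

SP_REGIMES = ("v4like", "v5like")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified protein sequence."""

    protein_id: str
    sequence: str
    genome_id: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """The ordered set of proteins of one genome.

    ``n_orfs`` is the denominator of every genome-level proportion
    (fraction of transmembrane proteins, fraction of Sec-secreted
    proteins), so the record count is authoritative.
    """

    genome_id: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.protein_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate protein_id in proteome: {sorted(dupes)}")
        self._index = {r.protein_id: r for r in self.records}

    @property
    def n_orfs(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self._index[protein_id]

    def lengths(self) -> dict[str, int]:
        return {r.protein_id: len(r) for r in self.records}


@dataclass(frozen=True)
class HomologHit:
    """Summary of one query-vs-subject alignment.

    ``similarity_pct`` is BLAST "positives" when available (ppos column
    or an in-house alignment), percent identity otherwise; the source is
    recorded in ``similarity_source``. ``rank_score`` is the bit score
    for parsed hits and the raw alignment score for in-house hits — the
    two scales must never be ranked together.
    """

    query_id: str
    subject_id: str
    similarity_pct: float
    coverage_pct: float
    query_start: int
    query_end: int
    rank_score: float
    subject_start: int | None = None
    similarity_source: str = "pident"
    score_scale: str = "bit"

    def __post_init__(self) -> None:
        if not (1 <= self.query_start <= self.query_end):
            raise ValueError(
                f"bad query span {self.query_start}..{self.query_end} "
                f"for {self.query_id}/{self.subject_id}"
            )
        if not 0.0 <= self.similarity_pct <= 100.0:
            raise ValueError(f"similarity_pct out of range: {self.similarity_pct}")
        if not 0.0 <= self.coverage_pct <= 100.0:
            raise ValueError(f"coverage_pct out of range: {self.coverage_pct}")


@dataclass(frozen=True)
class TmPrediction:
    """Transmembrane-helix call for one protein."""

    protein_id: str
    n_helices: int
    helix_spans: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_helices != len(self.helix_spans):
            raise ValueError(
                f"{self.protein_id}: n_helices={self.n_helices} but "
                f"{len(self.helix_spans)} spans"
            )
        prev_end = 0
        for s, e in self.helix_spans:
            if not (0 < s <= e):
                raise ValueError(f"{self.protein_id}: bad span {s}-{e}")
            if s <= prev_end:
                raise ValueError(f"{self.protein_id}: overlapping/unsorted spans")
            prev_end = e


@dataclass(frozen=True)
class SpPrediction:
    """Sec signal-peptide call for one protein under one predictor regime."""

    protein_id: str
    regime: str
    is_secreted: bool
    cleavage_pos: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in SP_REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.cleavage_pos is not None and not self.is_secreted:
            raise ValueError(f"{self.protein_id}: cleavage_pos on a negative call")


# ---------------------------------------------------------------------------
# FASTA


def _find_bad_char_line(path: Path, protein_id: str, bad: str) -> int:
    """Locate the first sequence line of ``protein_id`` containing ``bad``."""
    in_target = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_target = line[1:].split()[0] == protein_id if line[1:].split() else False
                continue
            if in_target and bad in line.upper():
                return lineno
    return -1


def read_fasta(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    Normalization: sequences are uppercased and terminal ``*`` stop
    symbols are stripped. The protein id is the first whitespace-delimited
    header token. Duplicate ids, internal stops and non-amino-acid
    characters are hard errors.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise FormatError(f"{path}: duplicate protein_id {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise FormatError(f"{path}: record {pid!r} has an empty sequence")
        bad = set(seq) - AMINO_ALPHABET
        if bad:
            ch = sorted(bad)[0]
            lineno = _find_bad_char_line(path, pid, ch)
            raise FormatError(
                f"{path}:{lineno}: invalid amino-acid character {ch!r} in {pid!r}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            ProteinRecord(protein_id=pid, sequence=seq, genome_id=genome_id, description=desc)
        )
    if not records:
        raise FormatError(f"{path}: no records")
    return Proteome(genome_id=genome_id, records=records)


def write_fasta(proteome: Proteome | Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA (id + description headers)."""
    records = proteome.records if isinstance(proteome, Proteome) else list(proteome)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular

_BLAST_COLS = 12  # standard outfmt 6; a 13th column is read as ppos


def parse_blast_tab(
    path: str | Path,
    query_lengths: Mapping[str, int],
    *,
    best_hsp_per_subject: bool = True,
    similarity_from: str = "auto",
) -> list[HomologHit]:
    """Parse BLAST tabular output (outfmt 6, optional 13th ppos column).

    ``similarity_pct`` is taken from the ppos column when present
    (``similarity_from="auto"``, the default), or forced to ``"pident"``
    / ``"ppos"``. Coverage is computed per HSP against
    ``query_lengths[query_id]``; self-hits are dropped; when
    ``best_hsp_per_subject`` only the highest-bit-score HSP of each
    query/subject pair is kept (ties: first occurrence).
    """
    if similarity_from not in ("auto", "pident", "ppos"):
        raise ValueError(f"similarity_from={similarity_from!r}")
    path = Path(path)
    hits: list[HomologHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < _BLAST_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_BLAST_COLS} tab-separated "
                    f"columns, got {len(cols)}"
                )
            qid, sid = cols[0], cols[1]
            if qid == sid:
                continue
            if qid not in query_lengths:
                raise FormatError(f"{path}:{lineno}: unknown query id {qid!r}")
            try:
                pident = float(cols[2])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart = int(cols[8])
                bitscore = float(cols[11])
                ppos = float(cols[12]) if len(cols) > _BLAST_COLS else None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            qlen = query_lengths[qid]
            if qend > qlen:
                raise FormatError(
                    f"{path}:{lineno}: qend {qend} exceeds query length {qlen}"
                )
            if similarity_from == "pident" or ppos is None:
                similarity, source = pident, "pident"
            else:
                similarity, source = ppos, "ppos"
            hits.append(
                HomologHit(
                    query_id=qid,
                    subject_id=sid,
                    similarity_pct=similarity,
                    coverage_pct=(qend - qstart + 1) / qlen * 100.0,
                    query_start=qstart,
                    query_end=qend,
                    rank_score=bitscore,
                    subject_start=sstart,
                    similarity_source=source,
                    score_scale="bit",
                )
            )
    if best_hsp_per_subject:
        best: dict[tuple[str, str], HomologHit] = {}
        for h in hits:
            key = (h.query_id, h.subject_id)
            if key not in best or h.rank_score > best[key].rank_score:
                best[key] = h
        hits = list(best.values())
    return hits


# ---------------------------------------------------------------------------
# TMHMM-short format

_TOPOLOGY_SPAN = re.compile(r"(\d+)-(\d+)")


def parse_tm_predictions(path: str | Path) -> list[TmPrediction]:
    """Parse TMHMM v2 short-format output.

    One tab-separated line per protein; helix count comes from the
    ``PredHel=`` field and spans from the ``Topology=`` string (e.g.
    ``i10-30o60-80i``).
    """
    path = Path(path)
    preds: list[TmPrediction] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            pid = cols[0].strip()
            if pid in seen:
                raise FormatError(f"{path}:{lineno}: protein {pid!r} listed twice")
            seen.add(pid)
            fields = {}
            for col in cols[1:]:
                if "=" in col:
                    k, v = col.split("=", 1)
                    fields[k.strip()] = v.strip()
            if "PredHel" not in fields:
                raise FormatError(f"{path}:{lineno}: missing PredHel= field")
            n_helices = int(fields["PredHel"])
            topology = fields.get("Topology", "")
            spans = tuple(
                (int(a), int(b)) for a, b in _TOPOLOGY_SPAN.findall(topology)
            )
            if len(spans) != n_helices:
                raise FormatError(
                    f"{path}:{lineno}: PredHel={n_helices} but topology "
                    f"{topology!r} has {len(spans)} spans"
                )
            preds.append(TmPrediction(protein_id=pid, n_helices=n_helices, helix_spans=spans))
    return preds


def write_tm_predictions(
    preds: Sequence[TmPrediction], lengths: Mapping[str, int], path: str | Path
) -> None:
    """Write TMHMM-short-compatible lines (the dialect ``parse_tm_predictions`` reads)."""
    with open(path, "w") as fh:
        for p in preds:
            topology = ""
            state = "i"
            for s, e in p.helix_spans:
                topology += f"{state}{s}-{e}"
                state = "o" if state == "i" else "i"
            topology += state
            exp_aa = sum(e - s + 1 for s, e in p.helix_spans)
            fh.write(
                f"{p.protein_id}\tlen={lengths[p.protein_id]}\tExpAA={exp_aa:.2f}\t"
                f"First60=0.00\tPredHel={p.n_helices}\tTopology={topology}\n"
            )


# ---------------------------------------------------------------------------
# Signal-peptide summary (two/three column TSV)


def parse_sp_predictions(path: str | Path, regime: str) -> list[SpPrediction]:
    """Parse the two-column SP summary: ``protein_id<TAB>YES|NO[<TAB>cleavage_pos]``."""
    if regime not in SP_REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    path = Path(path)
    preds: list[SpPrediction] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
            pid, verdict = cols[0].strip(), cols[1].strip().upper()
            if pid in seen:
                raise FormatError(f"{path}:{lineno}: protein {pid!r} listed twice")
            seen.add(pid)
            if verdict not in ("YES", "NO"):
                raise FormatError(f"{path}:{lineno}: verdict must be YES/NO, got {verdict!r}")
            secreted = verdict == "YES"
            cleavage = int(cols[2]) if secreted and len(cols) > 2 and cols[2].strip() else None
            preds.append(
                SpPrediction(
                    protein_id=pid, regime=regime, is_secreted=secreted, cleavage_pos=cleavage
                )
            )
    return preds


def write_sp_predictions(preds: Sequence[SpPrediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in preds:
            if p.is_secreted:
                pos = "" if p.cleavage_pos is None else f"\t{p.cleavage_pos}"
                fh.write(f"{p.protein_id}\tYES{pos}\n")
            else:
                fh.write(f"{p.protein_id}\tNO\n")
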