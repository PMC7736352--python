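"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* :func:`make_family` — a homolog family sharing one ancestral core
  domain, with point substitutions per member and N-terminal extensions
  planted on selected members. Cores mutate by substitution only, so a
  planted extension length is exactly recoverable by the screen; an
  optional indel rate relaxes that for robustness testing.
* :func:`make_proteome` — a proteome with chosen fractions of
  transmembrane proteins (one strongly hydrophobic 19-residue segment)
  and Sec-secreted proteins (a compliant n/h/c signal peptide whose
  h-region length splits the strict and permissive predictor regimes),
  plus mock predictor files that reflect the planted truth with
  configurable false-positive/false-negative rates.
* :func:`make_panel` — a reference panel of genome signatures drawn
  from a bivariate normal, with planted outlier points flagged in the
  truth table.

Every generator is a pure function of its spec (the seed included):
reruns are byte-identical. Planted feature counts are ``round(rate*n)``
so zero-error mock files reproduce the planted fractions exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_io import (
    ProteinRecord,
    Proteome,
    SpPrediction,
    TmPrediction,
    write_fasta,
    write_sp_predictions,
    write_tm_predictions,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# faces used for planted amphipathic extensions (assigned by helical angle)
_HYDRO_FACE = "ILF"
_POLAR_FACE = "KRE"

# residue pools for planted membrane features
_TM_POOL = "ILVF"
_SP_POLAR = "STNQ"


@dataclass(frozen=True)
class FamilySpec:
    """One homolog family with planted N-terminal extensions."""

    seed: int
    n_homologs: int = 12
    core_length: int = 200
    substitution_rate: float = 0.0
    nte_lengths: dict[int, int] = field(default_factory=dict)
    nte_composition: str = "random"
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 0.3:
            raise ValueError("substitution_rate must lie in [0, 0.3]")
        if any(v < 1 for v in self.nte_lengths.values()):
            raise ValueError("planted NTE lengths must be >= 1")
        if any(not 0 <= k < self.n_homologs for k in self.nte_lengths):
            raise ValueError("nte_lengths keys must index members")
        if self.nte_composition not in ("random", "amphipathic"):
            raise ValueError(f"unknown nte_composition {self.nte_composition!r}")


@dataclass
class Family:
    proteome: Proteome
    truth: pd.DataFrame  # member_id, planted_nte_len

    def write(self, fasta_path: str | Path, truth_path: str | Path | None = None) -> None:
        write_fasta(self.proteome, fasta_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    out = list(seq)
    for i, r in enumerate(out):
        if rng.random() < rate:
            choices = [a for a in AA20 if a != r]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _apply_indels(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    out: list[str] = []
    for r in seq:
        u = rng.random()
        if u < rate / 2:  # deletion
            continue
        out.append(r)
        if rate / 2 <= u < rate:  # insertion after
            out.append(AA20[rng.integers(len(AA20))])
    return "".join(out) or seq


def amphipathic_extension(rng: np.random.Generator, length: int, delta_deg: float = 100.0) -> str:
    """An extension with hydrophobic/polar faces alternating at the helical period."""
    out = []
    for i in range(1, length + 1):
        face = _HYDRO_FACE if math.cos(math.radians(i * delta_deg)) >= 0 else _POLAR_FACE
        out.append(face[rng.integers(len(face))])
    return "".join(out)


def make_family(spec: FamilySpec, genome_id: str = "synthetic") -> Family:
    """Generate a homolog family with planted N-terminal extensions."""
    rng = np.random.default_rng(spec.seed)
    core = _random_sequence(rng, spec.core_length)
    records: list[ProteinRecord] = []
    rows = []
    for i in range(spec.n_homologs):
        member_core = _mutate(rng, core, spec.substitution_rate)
        member_core = _apply_indels(rng, member_core, spec.indel_rate)
        nte_len = spec.nte_lengths.get(i, 0)
        if nte_len:
            if spec.nte_composition == "amphipathic":
                nte = amphipathic_extension(rng, nte_len)
            else:
                nte = _random_sequence(rng, nte_len)
        else:
            nte = ""
        pid = f"fam{spec.seed}_m{i:02d}"
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=nte + member_core,
                genome_id=genome_id,
                description=f"planted_nte={nte_len}",
            )
        )
        rows.append({"member_id": pid, "member_index": i, "planted_nte_len": nte_len})
    return Family(
        proteome=Proteome(genome_id=genome_id, records=records),
        truth=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Proteomes with planted membrane features


@dataclass(frozen=True)
class ProteomeSpec:
    """A proteome with planted TM and signal-peptide features.

    The planted fractions default to the replayed study-genome census
    (29.6% transmembrane proteins; 3.4% / 9.0% Sec substrates under the
    strict / permissive regimes). ``fp_rate``/``fn_rate`` corrupt the
    mock predictor files relative to the planted truth; at zero the
    mocks reproduce the truth exactly.
    """

    seed: int
    n_proteins: int = 1000
    min_length: int = 80
    max_length: int = 400
    frac_tm: float = 0.296
    frac_sp_v4: float = 0.034
    frac_sp_v5: float = 0.090
    fp_rate: float = 0.0
    fn_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.frac_tm, self.frac_sp_v4, self.frac_sp_v5, self.fp_rate, self.fn_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.frac_sp_v4 > self.frac_sp_v5:
            raise ValueError("frac_sp_v4 must not exceed frac_sp_v5")
        if self.frac_sp_v5 + self.frac_tm > 1.0:
            raise ValueError("frac_sp_v5 + frac_tm must not exceed 1")
        if self.min_length < 60 or self.max_length < self.min_length:
            raise ValueError("length range must satisfy 60 <= min <= max")


@dataclass
class SimulatedProteome:
    proteome: Proteome
    truth: pd.DataFrame  # protein_id, tm_planted, tm_span, sp_v4_planted, sp_v5_planted
    tm_mock: list[TmPrediction]
    sp_v4_mock: list[SpPrediction]
    sp_v5_mock: list[SpPrediction]

    def write(self, out_dir: str | Path, prefix: str | None = None) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.proteome.genome_id
        paths = {
            "fasta": out_dir / f"{prefix}.faa",
            "truth": out_dir / f"{prefix}.truth.tsv",
            "tm": out_dir / f"{prefix}.tmhmm.tsv",
            "sp_v4": out_dir / f"{prefix}.sp_v4like.tsv",
            "sp_v5": out_dir / f"{prefix}.sp_v5like.tsv",
        }
        write_fasta(self.proteome, paths["fasta"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_tm_predictions(self.tm_mock, self.proteome.lengths(), paths["tm"])
        write_sp_predictions(self.sp_v4_mock, paths["sp_v4"])
        write_sp_predictions(self.sp_v5_mock, paths["sp_v5"])
        return paths


def _plant_signal_peptide(rng: np.random.Generator, seq: list[str], h_len: int) -> int:
    """Overwrite the N-terminus with a compliant n/h/c signal peptide.

    Layout: M + K K + 2 polar (n-region, net charge +2), a hydrophobic
    run of ``h_len``, then the c-region S-S-A with cleavage after its
    final residue (the leading Ser terminates the hydrophobic run so
    the planted run length is exactly ``h_len``). Returns the cleavage
    position.
    """
    prefix = ["M", "K", "K"]
    prefix += [_SP_POLAR[rng.integers(len(_SP_POLAR))] for _ in range(2)]
    prefix += [_TM_POOL[rng.integers(len(_TM_POOL))] for _ in range(h_len)]
    prefix += ["S", "S", "A"]
    seq[: len(prefix)] = prefix
    # keep the residue after the h-region boundary polar so the planted
    # run length is exactly h_len within the rule search region
    if len(seq) > len(prefix):
        seq[len(prefix)] = _SP_POLAR[rng.integers(len(_SP_POLAR))]
    return len(prefix)


def make_proteome(spec: ProteomeSpec, genome_id: str = "sim") -> SimulatedProteome:
    """Generate a proteome with planted membrane features and mock predictor files."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    lengths = rng.integers(spec.min_length, spec.max_length + 1, size=n)
    n_tm = round(spec.frac_tm * n)
    n_v4 = round(spec.frac_sp_v4 * n)
    n_v5 = round(spec.frac_sp_v5 * n)
    order = rng.permutation(n)
    v5_set = set(order[:n_v5].tolist())
    v4_set = set(order[:n_v4].tolist())  # strict calls are a subset of permissive
    tm_set = set(order[n_v5 : n_v5 + n_tm].tolist())  # disjoint from SP proteins

    records: list[ProteinRecord] = []
    rows = []
    for i in range(n):
        pid = f"{genome_id}_p{i:05d}"
        seq = list(_random_sequence(rng, int(lengths[i])))
        cleavage = None
        if i in v5_set:
            h_len = 12 if i in v4_set else 9
            cleavage = _plant_signal_peptide(rng, seq, h_len)
        tm_span = None
        if i in tm_set:
            start = int(rng.integers(40, len(seq) - 19 + 1))
            seq[start : start + 19] = [
                _TM_POOL[rng.integers(len(_TM_POOL))] for _ in range(19)
            ]
            tm_span = (start + 1, start + 19)
        records.append(ProteinRecord(protein_id=pid, sequence="".join(seq), genome_id=genome_id))
        rows.append(
            {
                "protein_id": pid,
                "tm_planted": i in tm_set,
                "tm_start": tm_span[0] if tm_span else 0,
                "tm_end": tm_span[1] if tm_span else 0,
                "sp_v4_planted": i in v4_set,
                "sp_v5_planted": i in v5_set,
                "sp_cleavage": cleavage or 0,
            }
        )
    truth = pd.DataFrame(rows)

    def _flip(planted: bool) -> bool:
        if planted:
            return rng.random() >= spec.fn_rate
        return rng.random() < spec.fp_rate

    tm_mock, v4_mock, v5_mock = [], [], []
    for i, row in enumerate(rows):
        pid = row["protein_id"]
        tm_called = _flip(row["tm_planted"])
        if tm_called:
            span = (row["tm_start"], row["tm_end"]) if row["tm_planted"] else (10, 28)
            tm_mock.append(TmPrediction(protein_id=pid, n_helices=1, helix_spans=(span,)))
        else:
            tm_mock.append(TmPrediction(protein_id=pid, n_helices=0))
        for planted_key, out in (("sp_v4_planted", v4_mock), ("sp_v5_planted", v5_mock)):
            regime = "v4like" if planted_key == "sp_v4_planted" else "v5like"
            called = _flip(row[planted_key])
            out.append(
                SpPrediction(
                    protein_id=pid,
                    regime=regime,
                    is_secreted=called,
                    cleavage_pos=(row["sp_cleavage"] or 20) if called else None,
                )
            )
    return SimulatedProteome(
        proteome=Proteome(genome_id=genome_id, records=records),
        truth=truth,
        tm_mock=tm_mock,
        sp_v4_mock=v4_mock,
        sp_v5_mock=v5_mock,
    )


# ---------------------------------------------------------------------------
# Reference signature panels


@dataclass(frozen=True)
class PanelSpec:
    """A background cloud of genome signatures plus planted outliers."""

    seed: int
    n_genomes: int = 200
    mean: tuple[float, float] = (17.0, 1.1)
    covariance: tuple[tuple[float, float], tuple[float, float]] = ((9.0, 0.0), (0.0, 0.04))
    planted_outliers: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric 2x2")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive-definite")


def make_panel(spec: PanelSpec, group: str = "background") -> pd.DataFrame:
    """Draw a signature panel; planted outliers are flagged in the table."""
    rng = np.random.default_rng(spec.seed)
    cov = np.asarray(spec.covariance, dtype=float)
    draws = rng.multivariate_normal(np.asarray(spec.mean, dtype=float), cov, size=spec.n_genomes)
    rows = [
        {
            "genome_id": f"bg{i:04d}",
            "frac_tm_pct": float(x),
            "sec_ratio": float(y),
            "group": group,
            "planted_outlier": False,
        }
        for i, (x, y) in enumerate(draws)
    ]
    for j, (x, y) in enumerate(spec.planted_outliers):
        rows.append(
            {
                "genome_id": f"outlier{j:02d}",
                "frac_tm_pct": float(x),
                "sec_ratio": float(y),
                "group": "outlier",
                "planted_outlier": True,
            }
        )
    return pd.DataFrame(rows)
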