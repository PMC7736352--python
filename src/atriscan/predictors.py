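"""Rule-based transmembrane-helix and signal-peptide predictors.

These are deliberately simple, transparent stand-ins that let the
genome census run without external predictor binaries; every report
they feed labels them ``predictor=builtin``. The transmembrane scan is
a Kyte-Doolittle sliding-window hydropathy detector; the signal-peptide
rules encode the canonical tripartite architecture (positively charged
n-region, hydrophobic h-region, small-residue -3/-1 cleavage site).

Two signal-peptide regimes are provided, differing only in the minimum
h-region length (10 vs 8 residues). The permissive regime therefore
calls a superset of the strict regime's proteins on any input, which
reproduces the directional behaviour the census statistic is built on
(the newer predictor generation calling more Sec substrates than the
older one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .seq_io import ProteinRecord, Proteome, SpPrediction, TmPrediction

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

HYDROPHOBIC_RESIDUES = frozenset("AILMFVWC")
POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")
SMALL_C_RESIDUES = frozenset("AGSCT")


@dataclass(frozen=True)
class TmScanParams:
    """Sliding-window hydropathy scan (window must be odd)."""

    scale: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    window: int = 19
    threshold: float = 1.6
    min_gap: int = 5

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass(frozen=True)
class SpRuleParams:
    """Signal-peptide rule set for one predictor regime.

    ``h_min`` is the discriminating knob: the strict regime (v4like)
    requires a 10-residue hydrophobic run, the permissive one (v5like)
    8, so strict calls are a subset of permissive calls by construction.
    """

    regime: str
    n_region: int = 5
    h_min: int = 10
    max_cleavage: int = 35
    search_region: int = 25
    c_allowed: frozenset[str] = SMALL_C_RESIDUES

    def __post_init__(self) -> None:
        if self.h_min < 4:
            raise ValueError("h_min must be >= 4")


def sp_params(regime: str) -> SpRuleParams:
    """Default rule parameters for a named regime."""
    if regime == "v4like":
        return SpRuleParams(regime="v4like", h_min=10)
    if regime == "v5like":
        return SpRuleParams(regime="v5like", h_min=8)
    raise ValueError(f"unknown regime {regime!r}")


def predict_tm_segments(record: ProteinRecord, params: TmScanParams | None = None) -> TmPrediction:
    """Predict transmembrane helices by windowed mean hydropathy.

    Window centers whose mean hydropathy reaches the threshold form
    candidate segments; segments separated by fewer than ``min_gap``
    residues are merged. Proteins shorter than the window get zero
    helices.
    """
    params = params or TmScanParams()
    seq = record.sequence
    w = params.window
    if len(seq) < w:
        return TmPrediction(protein_id=record.protein_id, n_helices=0)
    values = np.array([params.scale[r] for r in seq])
    means = np.convolve(values, np.ones(w) / w, mode="valid")  # center index i -> seq[i:i+w]
    hot = means >= params.threshold
    spans: list[list[int]] = []
    for i, flag in enumerate(hot):
        if not flag:
            continue
        start, end = i + 1, i + w  # 1-based closed residue span of the window
        if spans and start <= spans[-1][1] + params.min_gap:
            spans[-1][1] = end
        else:
            spans.append([start, end])
    helix_spans = tuple((s, e) for s, e in spans)
    return TmPrediction(
        protein_id=record.protein_id, n_helices=len(helix_spans), helix_spans=helix_spans
    )


def _max_hydrophobic_run(segment: str) -> int:
    best = run = 0
    for r in segment:
        run = run + 1 if r in HYDROPHOBIC_RESIDUES else 0
        best = max(best, run)
    return best


def predict_signal_peptide(record: ProteinRecord, params: SpRuleParams) -> SpPrediction:
    """Apply the three signal-peptide rules to one protein.

    Secreted iff (1) the net charge of the first ``n_region`` residues
    is at least +1, (2) a hydrophobic run of ``h_min`` residues occurs
    within the first ``search_region`` residues, and (3) a cleavage
    position no later than ``max_cleavage`` has small residues at -3
    and -1. The earliest compliant position is reported as the cleavage
    site. Proteins shorter than 20 residues are never called.
    """
    seq = record.sequence
    negative = SpPrediction(protein_id=record.protein_id, regime=params.regime, is_secreted=False)
    if len(seq) < 20:
        return negative
    n_region = seq[: params.n_region]
    charge = sum(r in POSITIVE_RESIDUES for r in n_region) - sum(
        r in NEGATIVE_RESIDUES for r in n_region
    )
    if charge < 1:
        return negative
    if _max_hydrophobic_run(seq[: params.search_region]) < params.h_min:
        return negative
    for pos in range(3, min(params.max_cleavage, len(seq) - 1) + 1):
        if seq[pos - 3] in params.c_allowed and seq[pos - 1] in params.c_allowed:
            return SpPrediction(
                protein_id=record.protein_id,
                regime=params.regime,
                is_secreted=True,
                cleavage_pos=pos,
            )
    return negative


def predict_proteome(
    proteome: Proteome,
    tm_params: TmScanParams | None = None,
    sp_v4: SpRuleParams | None = None,
    sp_v5: SpRuleParams | None = None,
) -> tuple[list[TmPrediction], list[SpPrediction], list[SpPrediction]]:
    """Run all built-in predictors over a proteome (order-independent)."""
    tm_params = tm_params or TmScanParams()
    sp_v4 = sp_v4 or sp_params("v4like")
    sp_v5 = sp_v5 or sp_params("v5like")
    tm = [predict_tm_segments(r, tm_params) for r in proteome]
    v4 = [predict_signal_peptide(r, sp_v4) for r in proteome]
    v5 = [predict_signal_peptide(r, sp_v5) for r in proteome]
    return tm, v4, v5
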