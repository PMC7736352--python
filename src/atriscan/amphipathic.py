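"""Amphipathic-helix scoring of N-terminal extensions.

Uses the classical per-residue hydrophobic moment: for a window of N
residues with hydrophobicities H_i and a helical rotation of delta
degrees per residue (100 deg for an alpha helix),

    mu_H = sqrt( (sum_i H_i sin(i*delta))^2 + (sum_i H_i cos(i*delta))^2 ) / N

A window is amphipathic when its mean moment is high (hydrophobicity
segregates to one helix face) while its mean hydrophobicity stays
moderate (the helix is not simply a transmembrane stretch). The default
thresholds (mu_H >= 0.4, mean H <= 0.4 on the Eisenberg normalized
consensus scale) delimit the classical surface-seeking region of the
hydrophobic-moment plot.

An externally produced secondary-structure annotation (per-residue
H/E/C string) can restrict scanning to predicted helical stretches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

#: Eisenberg normalized consensus hydrophobicity scale
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}


@dataclass(frozen=True)
class MomentParams:
    """Hydrophobic-moment scan settings.

    ``delta_deg`` is the helical rotation per residue (100 deg for an
    ideal alpha helix, i.e. 3.6 residues per turn); ``window`` the helix
    length scored at a time (18 residues = five turns); thresholds as in
    the module docstring.
    """

    scale: Mapping[str, float] = field(default_factory=lambda: dict(EISENBERG))
    delta_deg: float = 100.0
    window: int = 18
    mu_threshold: float = 0.4
    h_max: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_deg < 360.0:
            raise ValueError("delta_deg must lie in (0, 360)")
        if self.window < 4:
            raise ValueError("window must be >= 4")


@dataclass(frozen=True)
class AmphipathicityResult:
    best_window_start: int | None
    mu_h: float
    mean_h: float
    is_amphipathic: bool


def hydrophobic_moment(window_sequence: str, params: MomentParams | None = None) -> float:
    """Mean hydrophobic moment per residue of one window."""
    params = params or MomentParams()
    if not window_sequence:
        raise ValueError("empty window")
    delta = math.radians(params.delta_deg)
    sin_sum = 0.0
    cos_sum = 0.0
    for i, residue in enumerate(window_sequence, start=1):
        try:
            h = params.scale[residue]
        except KeyError:
            raise ValueError(f"residue {residue!r} absent from hydrophobicity scale") from None
        sin_sum += h * math.sin(i * delta)
        cos_sum += h * math.cos(i * delta)
    return math.hypot(sin_sum, cos_sum) / len(window_sequence)


def mean_hydrophobicity(window_sequence: str, params: MomentParams | None = None) -> float:
    params = params or MomentParams()
    try:
        return sum(params.scale[r] for r in window_sequence) / len(window_sequence)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} absent from hydrophobicity scale") from None


def scan_nte(
    nte_sequence: str,
    params: MomentParams | None = None,
    secondary_structure: str | None = None,
) -> AmphipathicityResult:
    """Scan an NTE for its most amphipathic helix window.

    Windows of ``params.window`` residues slide by one; a sequence
    shorter than the window is evaluated as a single full-length window.
    Ties in moment go to the leftmost window. When a per-residue H/E/C
    ``secondary_structure`` string is supplied (e.g. parsed from an
    external secondary-structure predictor), only windows lying entirely
    within helical (H) stretches are considered.
    """
    params = params or MomentParams()
    n = len(nte_sequence)
    if n < 4:
        raise ValueError("NTE shorter than 4 residues cannot be scanned")
    if secondary_structure is not None and len(secondary_structure) != n:
        raise ValueError("secondary-structure annotation length mismatch")
    w = min(params.window, n)
    best: tuple[float, int] | None = None
    for start in range(0, n - w + 1):
        if secondary_structure is not None and any(
            c != "H" for c in secondary_structure[start : start + w]
        ):
            continue
        mu = hydrophobic_moment(nte_sequence[start : start + w], params)
        if best is None or mu > best[0]:
            best = (mu, start)
    if best is None:
        return AmphipathicityResult(
            best_window_start=None, mu_h=0.0, mean_h=0.0, is_amphipathic=False
        )
    mu, start = best
    mean_h = mean_hydrophobicity(nte_sequence[start : start + w], params)
    return AmphipathicityResult(
        best_window_start=start + 1,
        mu_h=mu,
        mean_h=mean_h,
        is_amphipathic=(mu >= params.mu_threshold and mean_h <= params.h_max),
    )


def read_secondary_structure(path) -> dict[str, str]:
    """Read a per-protein secondary-structure TSV (protein_id, H/E/C string)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pid, ss = cols
            if set(ss) - set("HEC"):
                raise ValueError(f"{path}:{lineno}: annotation must use H/E/C only")
            if pid in out:
                raise ValueError(f"{path}:{lineno}: protein {pid!r} listed twice")
            out[pid] = ss
    return out
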