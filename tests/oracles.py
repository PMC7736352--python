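"""Independent brute-force oracles used by the tests and acceptance checks.

These reimplement, from first principles and without touching the
package's code paths, the quantities the package computes:

- a pure-Python affine-gap (Gotoh) dynamic-programming score,
- the hydrophobic moment as a direct complex-exponential sum,
- the chi-square quantile with 2 degrees of freedom in closed form,
- brute-force hit filtering/ranking.
"""

from __future__ import annotations

import cmath
import math

NEG = float("-inf")


def gotoh_score(
    query: str,
    subject: str,
    matrix,
    gap_open: int = 11,
    gap_extend: int = 1,
    local: bool = True,
) -> float:
    """Optimal affine-gap alignment score; first gap residue costs open+extend."""
    n, m = len(query), len(subject)
    first = gap_open + gap_extend
    # H: best ending in match/mismatch or any state; E: gap in query (consume subject)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    if not local:
        for j in range(1, m + 1):
            E[0][j] = -(first + (j - 1) * gap_extend)
            H[0][j] = E[0][j]
        for i in range(1, n + 1):
            F[i][0] = -(first + (i - 1) * gap_extend)
            H[i][0] = F[i][0]
    best = 0.0 if local else NEG
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + matrix[qi, subject[j - 1]]
            h = max(diag, E[i][j], F[i][j])
            if local:
                h = max(h, 0.0)
                best = max(best, h)
            H[i][j] = h
    return best if local else H[n][m]


def moment_oracle(window: str, scale: dict[str, float], delta_deg: float = 100.0) -> float:
    """Hydrophobic moment via a direct complex sum |sum H_k e^{i k delta}| / N."""
    delta = math.radians(delta_deg)
    total = sum(scale[r] * cmath.exp(1j * k * delta) for k, r in enumerate(window, start=1))
    return abs(total) / len(window)


def chi2_quantile_2df(p: float) -> float:
    """Closed-form chi-square quantile, 2 degrees of freedom."""
    return -2.0 * math.log(1.0 - p)


def brute_force_filter(hits, min_similarity, min_coverage, top_k):
    """Reference filter+rank: strict thresholds, score-desc / id-asc, cap at top_k."""
    passing = [
        h for h in hits if h.similarity_pct > min_similarity and h.coverage_pct > min_coverage
    ]
    ordered = sorted(passing, key=lambda h: (-h.rank_score, h.subject_id))
    return ordered[:top_k]
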