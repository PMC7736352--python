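"""Genome membrane signatures and confidence-ellipse outlier detection.

A genome's membrane signature is the point

    x = percentage of proteins with >= 1 predicted transmembrane helix
    y = ratio of Sec-secreted-protein percentages called by the
        permissive vs strict signal-peptide regimes (v5like / v4like)

with all percentages taken over the total ORF count. A reference panel
of such points is modelled as a bivariate normal; the level-L
confidence ellipse is the contour where the squared Mahalanobis
distance equals the chi-square quantile with 2 degrees of freedom, and
genomes falling outside the 99.9% ellipse are flagged as structural
outliers. Genomes with unusual envelopes sit in the upper-right of this
plane: many membrane proteins and a strong excess of permissive-regime
signal-peptide calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .seq_io import Proteome, SpPrediction, TmPrediction

DEFAULT_LEVELS = (0.95, 0.999)


@dataclass(frozen=True)
class GenomeSignature:
    """Per-genome membrane signature (the scatter-plot coordinates)."""

    genome_id: str
    frac_tm_pct: float
    frac_sec_v4_pct: float
    frac_sec_v5_pct: float
    group: str = ""

    @property
    def sec_ratio(self) -> float | None:
        """v5like/v4like percentage ratio; None when the denominator is 0."""
        if self.frac_sec_v4_pct == 0:
            return None
        return self.frac_sec_v5_pct / self.frac_sec_v4_pct

    @property
    def xy(self) -> tuple[float, float] | None:
        r = self.sec_ratio
        return None if r is None else (self.frac_tm_pct, r)


@dataclass(frozen=True)
class EllipseModel:
    """Bivariate-normal reference model over (frac_tm_pct, sec_ratio)."""

    mean: np.ndarray
    covariance: np.ndarray
    levels: tuple[float, ...] = DEFAULT_LEVELS
    chi2_quantiles: dict[float, float] = field(default_factory=dict)
    n_reference: int = 0
    robust: bool = False


@dataclass(frozen=True)
class OutlierReport:
    genome_id: str
    mahalanobis_sq: float | None
    inside: dict[float, bool | None]
    frac_tm_percentile: float
    reason: str = ""


def genome_signature(
    proteome: Proteome,
    tm_preds: Iterable[TmPrediction],
    sp_preds_v4: Iterable[SpPrediction],
    sp_preds_v5: Iterable[SpPrediction],
    *,
    group: str = "",
) -> GenomeSignature:
    """Census a proteome into its membrane signature.

    Counts are over distinct proteins of the proteome; a protein with no
    prediction entry counts as negative; at most one prediction per
    protein and predictor is allowed.
    """
    n = proteome.n_orfs

    def _unique(preds, kind):
        seen = {}
        for p in preds:
            if p.protein_id not in proteome:
                continue
            if p.protein_id in seen:
                raise ValueError(f"duplicate {kind} prediction for {p.protein_id!r}")
            seen[p.protein_id] = p
        return seen

    tm = _unique(tm_preds, "TM")
    v4 = _unique(sp_preds_v4, "SP-v4like")
    v5 = _unique(sp_preds_v5, "SP-v5like")
    n_tm = sum(p.n_helices >= 1 for p in tm.values())
    n_v4 = sum(p.is_secreted for p in v4.values())
    n_v5 = sum(p.is_secreted for p in v5.values())
    return GenomeSignature(
        genome_id=proteome.genome_id,
        frac_tm_pct=n_tm / n * 100.0,
        frac_sec_v4_pct=n_v4 / n * 100.0,
        frac_sec_v5_pct=n_v5 / n * 100.0,
        group=group,
    )


def _as_points(signatures) -> np.ndarray:
    """Accept GenomeSignatures, (x, y) pairs or an (n, 2) array."""
    pts = []
    for s in signatures:
        if isinstance(s, GenomeSignature):
            xy = s.xy
            if xy is None:
                continue
            pts.append(xy)
        else:
            x, y = s
            pts.append((float(x), float(y)))
    return np.asarray(pts, dtype=float)


def fit_reference_ellipse(
    signatures: Iterable,
    levels: Sequence[float] = DEFAULT_LEVELS,
    *,
    robust: bool = False,
) -> EllipseModel:
    """Fit the bivariate-normal reference model of a genome panel.

    Plain sample mean / unbiased covariance by default (the standard
    confidence-ellipse construction); ``robust=True`` switches to a
    minimum-covariance-determinant fit. Panels with fewer than 3 usable
    points or a singular covariance are rejected.
    """
    pts = _as_points(signatures)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 reference signatures with defined sec_ratio, got {len(pts)}")
    if sorted(levels) != list(levels) or len(set(levels)) != len(levels):
        raise ValueError("levels must be strictly increasing")
    if robust:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(pts)
        mean, cov = mcd.location_, mcd.covariance_
    else:
        mean = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 1e-12 * max(eigvals.max(), 1.0):
        axis = "frac_tm_pct" if cov[0, 0] <= cov[1, 1] else "sec_ratio"
        raise ValueError(
            f"singular reference covariance (no spread along {axis}); "
            "cannot fit confidence ellipses"
        )
    quantiles = {lv: float(stats.chi2.ppf(lv, df=2)) for lv in levels}
    return EllipseModel(
        mean=mean,
        covariance=cov,
        levels=tuple(levels),
        chi2_quantiles=quantiles,
        n_reference=len(pts),
        robust=robust,
    )


def mahalanobis_sq(point: Sequence[float], model: EllipseModel) -> float:
    """Squared Mahalanobis distance of a point from the model mean."""
    d = np.asarray(point, dtype=float) - model.mean
    return float(d @ np.linalg.solve(model.covariance, d))


def classify_genome(
    sig: GenomeSignature,
    model: EllipseModel,
    reference: Iterable[GenomeSignature] = (),
) -> OutlierReport:
    """Place one genome relative to the reference ellipses.

    ``inside[L]`` is True when the squared Mahalanobis distance does not
    exceed the chi-square(2 df) quantile at level L. The transmembrane
    percentile is the share of reference genomes with strictly smaller
    frac_tm_pct. A genome with undefined sec_ratio gets null flags and a
    reason code instead of an error.
    """
    ref = list(reference)
    smaller = sum(r.frac_tm_pct < sig.frac_tm_pct for r in ref)
    percentile = smaller / len(ref) * 100.0 if ref else math.nan
    if sig.xy is None:
        return OutlierReport(
            genome_id=sig.genome_id,
            mahalanobis_sq=None,
            inside={lv: None for lv in model.levels},
            frac_tm_percentile=percentile,
            reason="undefined-sec-ratio",
        )
    m2 = mahalanobis_sq(sig.xy, model)
    return OutlierReport(
        genome_id=sig.genome_id,
        mahalanobis_sq=m2,
        inside={lv: m2 <= model.chi2_quantiles[lv] for lv in model.levels},
        frac_tm_percentile=percentile,
    )


def ellipse_boundary(model: EllipseModel, level: float, n_points: int = 256) -> np.ndarray:
    """Boundary polyline of the level-L ellipse (for scatter export/plotting)."""
    if level not in model.chi2_quantiles:
        q = float(stats.chi2.ppf(level, df=2))
    else:
        q = model.chi2_quantiles[level]
    theta = np.linspace(0.0, 2.0 * np.pi, n_points)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    chol = np.linalg.cholesky(model.covariance)
    return (model.mean[:, None] + math.sqrt(q) * (chol @ circle)).T
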