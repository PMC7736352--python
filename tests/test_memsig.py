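"""Genome signatures, confidence ellipses and outlier classification."""

import numpy as np
import pytest

from atriscan.memsig import (
    GenomeSignature,
    classify_genome,
    ellipse_boundary,
    fit_reference_ellipse,
    genome_signature,
    mahalanobis_sq,
)
from atriscan.seq_io import ProteinRecord, Proteome, SpPrediction, TmPrediction
from atriscan.simulate import PanelSpec, ProteomeSpec, make_panel, make_proteome

from oracles import chi2_quantile_2df


def _proteome(n):
    return Proteome(
        genome_id="g",
        records=[ProteinRecord(protein_id=f"p{i}", sequence="MKVLT", genome_id="g") for i in range(n)],
    )


def _tm(pid, n_helices):
    spans = tuple((1 + 25 * k, 19 + 25 * k) for k in range(n_helices))
    return TmPrediction(protein_id=pid, n_helices=n_helices, helix_spans=spans)


def _sp(pid, regime, yes):
    return SpPrediction(protein_id=pid, regime=regime, is_secreted=yes,
                        cleavage_pos=20 if yes else None)


class TestGenomeSignature:
    def test_fraction_arithmetic_over_orf_count(self):
        prot = _proteome(10)
        tm = [_tm(f"p{i}", 1 if i < 3 else 0) for i in range(10)]
        sig = genome_signature(prot, tm, [], [])
        assert sig.frac_tm_pct == pytest.approx(30.0)
        assert sig.frac_sec_v4_pct == 0.0

    def test_sec_ratio_of_replayed_census_percentages(self):
        sig = GenomeSignature("g", frac_tm_pct=29.6, frac_sec_v4_pct=3.4, frac_sec_v5_pct=9.0)
        assert sig.sec_ratio == pytest.approx(2.6470588235, abs=1e-9)

    def test_zero_strict_regime_gives_undefined_ratio(self):
        sig = GenomeSignature("g", 10.0, 0.0, 5.0)
        assert sig.sec_ratio is None and sig.xy is None

    def test_missing_predictions_count_as_negative(self):
        prot = _proteome(4)
        sig = genome_signature(prot, [_tm("p0", 2)], [_sp("p1", "v4like", True)],
                               [_sp("p1", "v5like", True)])
        assert sig.frac_tm_pct == pytest.approx(25.0)
        assert sig.frac_sec_v4_pct == pytest.approx(25.0)

    def test_duplicate_predictions_rejected(self):
        prot = _proteome(2)
        with pytest.raises(ValueError, match="duplicate"):
            genome_signature(prot, [_tm("p0", 1), _tm("p0", 0)], [], [])

    def test_zero_error_mocks_reproduce_planted_rates_exactly(self):
        sim = make_proteome(ProteomeSpec(seed=3), genome_id="rt")
        sig = genome_signature(sim.proteome, sim.tm_mock, sim.sp_v4_mock, sim.sp_v5_mock)
        assert sig.frac_tm_pct == pytest.approx(29.6)
        assert sig.frac_sec_v4_pct == pytest.approx(3.4)
        assert sig.frac_sec_v5_pct == pytest.approx(9.0)


class TestEllipseFit:
    def test_chi_square_boundaries_match_closed_form_quantiles(self, rng):
        pts = rng.multivariate_normal([0, 0], np.eye(2), size=500)
        model = fit_reference_ellipse(pts)
        assert model.chi2_quantiles[0.95] == pytest.approx(chi2_quantile_2df(0.95), abs=1e-9)
        assert model.chi2_quantiles[0.95] == pytest.approx(5.991464547, abs=1e-6)
        assert model.chi2_quantiles[0.999] == pytest.approx(13.815510558, abs=1e-6)

    def test_duplicated_points_give_singular_covariance_error(self):
        with pytest.raises(ValueError, match="singular"):
            fit_reference_ellipse([(1.0, 2.0), (1.0, 2.0), (1.0, 2.0)])

    def test_too_small_panel_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_reference_ellipse([(1.0, 2.0), (3.0, 4.0)])

    def test_monte_carlo_coverage_at_both_levels(self):
        """Fractions inside the fitted 95% / 99.9% ellipses match the levels."""
        rng = np.random.default_rng(7)
        pts = rng.multivariate_normal([17.0, 1.1], [[9.0, 0.5], [0.5, 0.04]], size=10000)
        model = fit_reference_ellipse(pts)
        m2 = np.array([mahalanobis_sq(p, model) for p in pts])
        frac95 = float((m2 <= model.chi2_quantiles[0.95]).mean())
        frac999 = float((m2 <= model.chi2_quantiles[0.999]).mean())
        assert 0.945 <= frac95 <= 0.955
        assert 0.9985 <= frac999 <= 0.9995

    def test_affine_translation_equivariance(self, rng):
        pts = rng.multivariate_normal([5.0, 2.0], [[4.0, 1.0], [1.0, 2.0]], size=100)
        shift = np.array([10.0, -3.0])
        model = fit_reference_ellipse(pts)
        shifted = fit_reference_ellipse(pts + shift)
        assert np.allclose(shifted.mean, model.mean + shift)
        assert np.allclose(shifted.covariance, model.covariance)
        test_point = np.array([7.0, 1.0])
        assert mahalanobis_sq(test_point + shift, shifted) == pytest.approx(
            mahalanobis_sq(test_point, model)
        )

    def test_robust_fit_resists_planted_outliers(self, rng):
        pts = rng.multivariate_normal([10.0, 1.0], np.diag([1.0, 0.01]), size=100)
        contaminated = np.vstack([pts, [[60.0, 9.0]] * 5])
        robust = fit_reference_ellipse(contaminated, robust=True)
        plain = fit_reference_ellipse(contaminated)
        assert abs(robust.mean[0] - 10.0) < abs(plain.mean[0] - 10.0)

    def test_boundary_points_lie_at_the_level_quantile(self, rng):
        pts = rng.multivariate_normal([3.0, 1.0], [[2.0, 0.3], [0.3, 0.5]], size=50)
        model = fit_reference_ellipse(pts)
        for xy in ellipse_boundary(model, 0.95, n_points=32):
            assert mahalanobis_sq(xy, model) == pytest.approx(
                model.chi2_quantiles[0.95], rel=1e-9
            )


class TestClassifyGenome:
    @staticmethod
    def _model(rng):
        pts = rng.multivariate_normal([15.0, 1.1], [[4.0, 0.0], [0.0, 0.04]], size=300)
        return fit_reference_ellipse(pts), pts

    def test_point_at_the_mean_is_inside_everything(self, rng):
        model, _ = self._model(rng)
        sig = GenomeSignature("g", float(model.mean[0]), 1.0, float(model.mean[1]))
        rep = classify_genome(sig, model)
        assert rep.mahalanobis_sq == pytest.approx(0.0, abs=1e-12)
        assert all(rep.inside.values())

    def test_point_between_the_quantiles_is_outside_95_inside_999(self, rng):
        model, _ = self._model(rng)
        # walk along the x axis to a squared distance of ~9 (between 5.99 and 13.82)
        x = model.mean[0] + 3.0 * np.sqrt(model.covariance[0, 0])
        sig = GenomeSignature("g", float(x), 1.0, float(model.mean[1]))
        rep = classify_genome(sig, model)
        assert 5.992 < rep.mahalanobis_sq < 13.815
        assert not rep.inside[0.95] and rep.inside[0.999]

    def test_inside_flags_are_monotone_in_level(self, rng):
        model, pts = self._model(rng)
        for x, y in pts[:50]:
            rep = classify_genome(GenomeSignature("g", x, 1.0, y), model)
            assert (not rep.inside[0.95]) or rep.inside[0.999]

    def test_undefined_ratio_reports_reason_not_error(self, rng):
        model, _ = self._model(rng)
        rep = classify_genome(GenomeSignature("g", 10.0, 0.0, 5.0), model)
        assert rep.mahalanobis_sq is None
        assert rep.inside[0.95] is None
        assert rep.reason == "undefined-sec-ratio"

    def test_percentile_is_strict_share_and_bounded(self, rng):
        model, _ = self._model(rng)
        ref = [GenomeSignature(f"r{i}", float(x), 1.0, 1.1) for i, x in enumerate([10, 12, 14, 16])]
        rep = classify_genome(GenomeSignature("g", 15.0, 1.0, 1.1), model, ref)
        assert rep.frac_tm_percentile == pytest.approx(75.0)
        rep_low = classify_genome(GenomeSignature("g", 1.0, 1.0, 1.1), model, ref)
        assert rep_low.frac_tm_percentile == 0.0

    def test_adding_self_to_reference_never_raises_percentile(self, rng):
        model, _ = self._model(rng)
        ref = [GenomeSignature(f"r{i}", float(x), 1.0, 1.1) for i, x in enumerate([10, 12, 14])]
        sig = GenomeSignature("g", 13.0, 1.0, 1.1)
        before = classify_genome(sig, model, ref).frac_tm_percentile
        after = classify_genome(sig, model, ref + [sig]).frac_tm_percentile
        assert after <= before


class TestOutlierReplay:
    def test_planted_far_outlier_sits_outside_the_999_ellipse(self):
        spec = PanelSpec(
            seed=5,
            n_genomes=300,
            mean=(17.0, 1.1),
            covariance=((9.0, 0.0), (0.0, 0.04)),
            planted_outliers=((47.0, 3.1),),  # +10 SD on both axes
        )
        panel = make_panel(spec)
        background = panel[~panel.planted_outlier]
        model = fit_reference_ellipse(list(zip(background.frac_tm_pct, background.sec_ratio)))
        outlier = panel[panel.planted_outlier].iloc[0]
        m2 = mahalanobis_sq((outlier.frac_tm_pct, outlier.sec_ratio), model)
        assert m2 > 13.8155  # far beyond chi2(0.999, 2 df)

    def test_rt761_like_genome_outside_background_cloud(self):
        """Replayed census signature is flagged against a typical background."""
        sim = make_proteome(ProteomeSpec(seed=3), genome_id="rt")
        sig = genome_signature(sim.proteome, sim.tm_mock, sim.sp_v4_mock, sim.sp_v5_mock)
        panel = make_panel(PanelSpec(seed=6, n_genomes=300))
        background = [
            GenomeSignature(r.genome_id, r.frac_tm_pct, 1.0, r.sec_ratio)
            for r in panel.itertuples()
        ]
        model = fit_reference_ellipse(background)
        rep = classify_genome(sig, model, background)
        assert not rep.inside[0.999]
        assert rep.frac_tm_percentile == 100.0
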