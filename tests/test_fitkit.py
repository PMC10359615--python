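"""Fitting layer: noiseless round trips, seeded noisy recovery, warning logic."""

import numpy as np
import pytest

from apekin import fitkit, synthgen
from apekin.fitkit import (
    BindingTitration,
    FretTrace,
    TimeCourse,
    TitrationCurve,
    aggregate_replicates,
    calibrate_contrast,
    calibrate_from_peaks,
    emsa_fraction_bound,
    fit_burst,
    fit_double_exp,
    fit_gaussian_mixture,
    fit_morrison,
    fit_single_exp,
    fold_change_with_error,
    inhibition_midpoint,
    normalize_titration,
    plateau_efret,
    population_fractions,
)
from apekin.models import BiexpParams, GaussianComponent, KineticParams
from apekin.synthgen import ExperimentDesign, NoiseModel

DESIGN = ExperimentDesign()


def _mt_timecourse(truth: KineticParams, seed=None, cv=0.03):
    noise = None if seed is None else NoiseModel(seed=seed, cv=cv)
    return synthgen.gen_timecourse(truth, DESIGN, noise)


class TestFitBurst:
    def test_noiseless_round_trip(self):
        truth = KineticParams(A=30.0, kobs=10.0, vss=81.0)
        res = fit_burst(_mt_timecourse(truth))
        assert res.params.A == pytest.approx(30.0, rel=1e-6)
        assert res.params.kobs == pytest.approx(10.0, rel=1e-6)
        assert res.params.vss == pytest.approx(81.0, rel=1e-6)
        assert res.params.kss == pytest.approx(2.7, rel=1e-6)

    def test_noisy_recovery_flags_low_separation(self):
        """At kobs/kss = 3.7 the burst and steady phases overlap: kobs is
        still recovered within 10% but the fit warns about it."""
        truth = KineticParams(A=30.0, kobs=10.0, vss=81.0)
        res = fit_burst(_mt_timecourse(truth, seed=1))
        assert res.params.kobs == pytest.approx(10.0, rel=0.10)
        assert "low-separation" in res.warnings

    def test_fast_substrate_no_warning(self):
        """kobs/kss = 76 for the duplex-like truth: phases well separated,
        recovery within 15% from the rapid-quench grid, no warning."""
        truth = KineticParams(A=30.0, kobs=129.0, vss=51.0)
        res = fit_burst(_mt_timecourse(truth, seed=1))
        assert res.params.kobs == pytest.approx(129.0, rel=0.15)
        assert "low-separation" not in res.warnings

    def test_requires_regime_and_points(self):
        truth = KineticParams(A=30.0, kobs=10.0, vss=81.0)
        tc = _mt_timecourse(truth)
        tc.regime = "single_turnover"
        with pytest.raises(ValueError):
            fit_burst(tc)
        few = TimeCourse(t=[0.1, 0.2, 0.3, 0.4, 0.5], product=[1, 2, 3, 4, 5],
                         replicate=[0] * 5, regime="multiple_turnover", E0=30, S0=100)
        with pytest.raises(ValueError):
            fit_burst(few)


class TestFitSingleExp:
    def test_noiseless_round_trip(self):
        truth = KineticParams(A=50.0, kobs=13.6, vss=0.0)
        tc = synthgen.gen_timecourse(truth, DESIGN, regime="single_turnover")
        res = fit_single_exp(tc)
        assert res.params.A == pytest.approx(50.0, rel=1e-6)
        assert res.params.kobs == pytest.approx(13.6, rel=1e-6)

    def test_noisy_recovery(self):
        truth = KineticParams(A=50.0, kobs=13.6, vss=0.0)
        tc = synthgen.gen_timecourse(truth, DESIGN, NoiseModel(seed=2),
                                     regime="single_turnover")
        res = fit_single_exp(tc)
        assert res.params.kobs == pytest.approx(13.6, rel=0.10)

    def test_misspecification_flagged_by_runs_test(self):
        """A single exponential forced onto well-separated biphasic data
        leaves sign-correlated residuals; the runs test flags it."""
        truth = BiexpParams(A=40.0, k1=0.05, B=10.0, k2=2.0)
        tc = synthgen.gen_timecourse(truth, DESIGN, NoiseModel(seed=5, cv=0.01),
                                     regime="single_turnover")
        res = fit_single_exp(tc)
        assert "residual-structure" in res.warnings


class TestFitDoubleExp:
    truth = BiexpParams(A=40.0, k1=0.05, B=10.0, k2=2.0)

    def test_noiseless_round_trip_and_major_rate(self):
        tc = synthgen.gen_timecourse(self.truth, DESIGN, regime="single_turnover")
        res = fit_double_exp(tc)
        assert isinstance(res.params, BiexpParams)
        assert res.params.A == pytest.approx(40.0, rel=1e-5)
        assert res.params.k1 == pytest.approx(0.05, rel=1e-5)
        assert res.params.B == pytest.approx(10.0, rel=1e-5)
        assert res.params.k2 == pytest.approx(2.0, rel=1e-5)
        assert res.params.major_rate == pytest.approx(0.05, rel=1e-5)

    def test_degenerate_truth_falls_back_to_single(self):
        single = KineticParams(A=50.0, kobs=0.5, vss=0.0)
        tc = synthgen.gen_timecourse(single, DESIGN, regime="single_turnover")
        res = fit_double_exp(tc)
        assert "degenerate-biexp" in res.warnings
        assert isinstance(res.params, KineticParams)
        assert res.params.kobs == pytest.approx(0.5, rel=1e-4)

    def test_noisy_recovery_of_major_rate(self):
        tc = synthgen.gen_timecourse(self.truth, DESIGN, NoiseModel(seed=3, cv=0.03),
                                     regime="single_turnover")
        res = fit_double_exp(tc)
        assert res.params.major_rate == pytest.approx(0.05, rel=0.15)


class TestFitMorrison:
    def test_noiseless_round_trip(self):
        tit = synthgen.gen_emsa_titration(22.0, DESIGN)
        res = fit_morrison(tit)
        assert res.params.KD_app == pytest.approx(22.0, rel=1e-4)

    def test_noisy_recovery(self):
        tit = synthgen.gen_emsa_titration(22.0, DESIGN, NoiseModel(seed=4))
        res = fit_morrison(tit)
        assert res.params.KD_app == pytest.approx(22.0, rel=0.20)
        assert "tight-binding" not in res.warnings

    def test_tight_binding_regime_warns(self):
        """KD below the 5 nM probe DNA: the titration cannot resolve the
        affinity and the identifiability warning fires."""
        tit = synthgen.gen_emsa_titration(0.4, DESIGN, NoiseModel(seed=4))
        res = fit_morrison(tit)
        assert res.converged
        assert "tight-binding" in res.warnings

    def test_saturation_only_rejected(self):
        AT = np.geomspace(500, 2000, 8)
        tit = BindingTitration(AT=AT, bound=np.full(8, 4.99), replicate=np.zeros(8),
                               BT=5.0)
        with pytest.raises(ValueError, match="saturation-only"):
            fit_morrison(tit)


class TestEmsaFractionBound:
    @pytest.mark.parametrize("free, total, expected", [(1200.0, 1200.0, 0.0),
                                                       (0.0, 1200.0, 5.0),
                                                       (300.0, 1200.0, 3.75)])
    def test_values(self, free, total, expected):
        assert emsa_fraction_bound(free, total, BT=5.0) == pytest.approx(expected)

    def test_free_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            emsa_fraction_bound(1300.0, 1200.0, BT=5.0)


class TestPlateau:
    def test_constant_trace(self, flat_trace):
        t, i563, i665 = flat_trace(0.475)
        mean, sd = plateau_efret(FretTrace(t=t, I563=np.full_like(t, i563),
                                           I665=np.full_like(t, i665)))
        assert mean == pytest.approx(0.475)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_exponential_settling(self):
        t = np.arange(0.0, 300.0, 0.17)
        e = 0.3 + 0.175 * np.exp(-t / 5.0)
        mean, _sd = plateau_efret(FretTrace(t=t, I563=(1 - e) * 1e3, I665=e * 1e3))
        assert mean == pytest.approx(0.300, abs=0.002)

    def test_persistent_drift_has_no_plateau(self):
        t = np.arange(0.0, 300.0, 0.17)
        e = 0.4 * (1.0 + 0.05 * t / 60.0)  # 5% per minute, never settles
        with pytest.raises(RuntimeError, match="no plateau"):
            plateau_efret(FretTrace(t=t, I563=(1 - e) * 1e3, I665=e * 1e3))

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 30.0, 0.17)
        with pytest.raises(ValueError):
            plateau_efret(FretTrace(t=t, I563=np.ones_like(t), I665=np.ones_like(t)))


class TestTitrationAnalysis:
    def test_normalize_anchors_and_midpoint_value(self):
        curve = TitrationCurve(x=[0.0, 1.0, 2.0], y=[0.475, 0.3395, 0.204],
                               ymax=0.475, ymin=0.204)
        norm = normalize_titration(curve)
        assert norm.y[0] == pytest.approx(1.0)
        assert norm.y[1] == pytest.approx(0.5)
        assert norm.y[2] == pytest.approx(0.0, abs=1e-12)

    def test_normalize_requires_span(self):
        curve = TitrationCurve(x=[0.0, 1.0], y=[0.3, 0.3], ymax=0.2, ymin=0.2)
        with pytest.raises(ValueError):
            normalize_titration(curve)

    def test_normalize_round_trip(self):
        curve = synthgen.gen_fret_exchange_titration()
        norm = normalize_titration(curve)
        back = norm.y * (curve.ymax - curve.ymin) + curve.ymin
        np.testing.assert_allclose(back, curve.y, rtol=1e-12)

    def test_midpoint_of_proportional_partitioning(self):
        curve = synthgen.gen_competition_titration(L=25.0)
        assert inhibition_midpoint(curve) == pytest.approx(0.50, abs=1e-3)

    def test_midpoint_symmetric_bracket(self):
        curve = TitrationCurve(x=[0.4, 0.6], y=[0.6, 0.4])
        assert inhibition_midpoint(curve) == pytest.approx(0.5)

    def test_floored_curve_not_bracketed(self):
        """A titration that plateaus at 55% (partial exchange) never
        crosses the 50% midpoint."""
        x = np.linspace(0.0, 0.9, 10)
        y = np.maximum(1.0 - x, 0.55)
        with pytest.raises(ValueError, match="not bracketed"):
            inhibition_midpoint(TitrationCurve(x=x, y=y))

    def test_non_monotone_rejected_with_index(self):
        curve = TitrationCurve(x=[0.0, 0.2, 0.4, 0.6], y=[1.0, 0.7, 0.8, 0.3])
        with pytest.raises(ValueError, match="index 2"):
            inhibition_midpoint(curve)


def _hist(events, bins=80):
    counts, edges = np.histogram(events, bins=bins)
    return 0.5 * (edges[:-1] + edges[1:]), counts


class TestGaussianMixtureFit:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(5)
        x = np.linspace(80.0, 220.0, 60)
        clean = 200.0 * np.exp(-(((x - 150.0) / 15.0) ** 2))
        counts = rng.poisson(np.maximum(clean, 0.0))
        res = fit_gaussian_mixture(x, counts, n=1)
        assert res.params[0].b == pytest.approx(150.0, abs=2.0)

    def test_two_component_recovery(self):
        events = synthgen.gen_mass_events([0.9, 0.1], [150.0, 250.0], [12.0, 12.0],
                                          5000, seed=6)
        centers, counts = _hist(events)
        res = fit_gaussian_mixture(centers, counts, n=2)
        assert res.params[0].b == pytest.approx(150.0, abs=5.0)
        assert res.params[1].b == pytest.approx(250.0, abs=5.0)

    def test_overfit_single_peak_warns_collapse(self):
        events = synthgen.gen_mass_events([1.0], [150.0], [12.0], 5000, seed=7)
        centers, counts = _hist(events)
        res = fit_gaussian_mixture(centers, counts, n=2)
        assert "component-collapse" in res.warnings

    def test_input_validation(self):
        x = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            fit_gaussian_mixture(x, np.ones_like(x), n=4)
        with pytest.raises(ValueError):
            fit_gaussian_mixture(x[:10], np.ones(10), n=1)


class TestPopulationFractions:
    def test_single_component_is_unity(self):
        assert population_fractions([GaussianComponent(1.0, 150.0, 10.0)])[0] == 1.0

    def test_proportional_areas(self):
        comps = [GaussianComponent(9.0, 100.0, 10.0), GaussianComponent(1.0, 200.0, 10.0)]
        np.testing.assert_allclose(population_fractions(comps), [0.9, 0.1])

    def test_sums_to_one_exactly(self):
        comps = [GaussianComponent(3.3, 100.0, 7.1), GaussianComponent(1.7, 180.0, 9.2),
                 GaussianComponent(0.4, 260.0, 11.0)]
        assert population_fractions(comps).sum() == pytest.approx(1.0, abs=1e-15)

    def test_end_to_end_population_recovery(self):
        events = synthgen.gen_mass_events([0.9, 0.1], [150.0, 250.0], [12.0, 12.0],
                                          5000, seed=9)
        centers, counts = _hist(events)
        res = fit_gaussian_mixture(centers, counts, n=2)
        fracs = population_fractions(res.params)
        assert fracs[0] == pytest.approx(0.90, abs=0.03)
        assert fracs[1] == pytest.approx(0.10, abs=0.03)

    def test_zero_areas_rejected(self):
        with pytest.raises(ValueError):
            population_fractions([GaussianComponent(0.0, 1.0, 1.0)])


class TestCalibration:
    def test_affine_round_trip_from_peaks(self):
        masses = np.array([56.0, 112.0, 224.0])
        contrasts = masses * 0.002 + 0.001
        cal = calibrate_from_peaks(contrasts, masses)
        assert cal.slope == pytest.approx(500.0, rel=1e-6)
        assert cal.intercept == pytest.approx(-0.5, abs=1e-6)

    def test_two_peaks_interpolate_exactly(self):
        cal = calibrate_from_peaks([0.1, 0.3], [50.0, 150.0])
        np.testing.assert_allclose(cal([0.1, 0.3]), [50.0, 150.0], rtol=1e-12)
        assert cal.residuals == (0.0, 0.0)

    def test_noisy_three_peak_standard(self):
        rng = np.random.default_rng(7)
        masses = np.array([56.0, 112.0, 224.0])
        events = np.concatenate([
            rng.normal(m * 0.002 + 0.001, 0.008, 1500) for m in masses
        ])
        cal = calibrate_contrast(events, masses)
        mapped = cal(masses * 0.002 + 0.001)
        np.testing.assert_allclose(mapped, masses, rtol=0.03)

    def test_single_peak_underdetermined(self):
        with pytest.raises(ValueError):
            calibrate_from_peaks([0.1], [50.0])


class TestReplicateStats:
    def test_exact_values(self):
        s = aggregate_replicates([1.0, 2.0, 3.0])
        assert (s.mean, s.sd) == (2.0, 1.0)
        assert s.sem == pytest.approx(0.5773502691896258)
        assert s.warnings == ()

    def test_degenerate_and_small_n(self):
        assert aggregate_replicates([5.0, 5.0, 5.0]).sd == 0.0
        assert aggregate_replicates([1.0, 2.0]).warnings
        with pytest.raises(ValueError):
            aggregate_replicates([1.0])


class TestFoldChangeError:
    def test_ratio_propagation(self):
        fc = fold_change_with_error((129.0, 24.0), (10.0, 1.0))
        assert fc.fold == pytest.approx(12.9)
        assert fc.se == pytest.approx(2.7247, abs=1e-3)

    def test_zero_errors_propagate_to_zero(self):
        assert fold_change_with_error((10.0, 0.0), (5.0, 0.0)).se == 0.0

    def test_extreme_ratio(self):
        fc = fold_change_with_error((2.0, 0.2), (0.001, 0.0001))
        assert fc.fold == pytest.approx(2000.0)
        assert fc.se == pytest.approx(2000.0 * np.sqrt(0.02), rel=1e-6)
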