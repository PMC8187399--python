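import numpy as np
import pandas as pd
import pytest

from confobs.nmr import (
    CalibrationModel,
    DecayCurve,
    FitError,
    PeakTable,
    calibrate_sehplc,
    fit_stejskal_tanner,
    fit_t2,
    hydrodynamic_radius,
    mean_residue_ellipticity,
    round_rh,
    sehplc_rh,
    stoichiometry_from_peaks,
)
from confobs.synthetic import gen_cpmg_decay, gen_pfg_decay


class TestDiffusionFits:
    def test_single_component_recovery_with_noise(self):
        g = np.geomspace(0.01, 0.28, 60)
        curve = gen_pfg_decay(2.162e-10, g, 0.005, 0.1, noise_sd=0.01, seed=8)
        fit = fit_stejskal_tanner(curve)
        assert fit.d[0] == pytest.approx(2.162e-10, rel=0.05)
        assert fit.fractions.sum() == pytest.approx(1.0)

    def test_two_component_mixture_noiseless_is_exact(self):
        g = np.geomspace(0.005, 0.4, 60)
        d_fast, d_slow = 1e-9, 1e-10
        from confobs.nmr import st_kernel

        k = st_kernel(g, 0.005, 0.1)
        clean = 0.9 * np.exp(-d_slow * k) + 0.1 * np.exp(-d_fast * k)
        curve = DecayCurve(g, clean, kind="pfg", delta=0.005, big_delta=0.1)
        fit = fit_stejskal_tanner(curve, n_components=2)
        assert fit.d[0] == pytest.approx(d_fast, rel=1e-6)  # ordered by D
        assert fit.d[1] == pytest.approx(d_slow, rel=1e-6)
        assert fit.fractions[1] == pytest.approx(0.9, abs=1e-6)

    def test_two_component_mixture_resolved_at_one_percent_noise(self):
        # 90/10 mixture, tenfold D contrast. At 1% multiplicative noise
        # the 10% fast component's D carries ~10% statistical scatter
        # (its amplitude is only 10x the noise floor), so the dominant
        # component is held to 5% and the minor one to its Monte-Carlo
        # precision.
        g = np.geomspace(0.005, 0.4, 60)
        d_fast, d_slow = 1e-9, 1e-10
        from confobs.nmr import st_kernel

        k = st_kernel(g, 0.005, 0.1)
        clean = 0.9 * np.exp(-d_slow * k) + 0.1 * np.exp(-d_fast * k)
        err_fast, err_slow, frac = [], [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            curve = DecayCurve(g, clean * (1 + 0.01 * rng.standard_normal(g.size)),
                               kind="pfg", delta=0.005, big_delta=0.1)
            fit = fit_stejskal_tanner(curve, n_components=2)
            err_fast.append(fit.d[0] / d_fast - 1.0)
            err_slow.append(fit.d[1] / d_slow - 1.0)
            frac.append(fit.fractions[1])
        assert np.median(np.abs(err_slow)) < 0.05
        assert np.median(np.abs(err_fast)) < 0.15
        # unbiased: mean errors consistent with zero at 3 SE
        assert abs(np.mean(err_fast)) < 3 * np.std(err_fast) / np.sqrt(30)
        assert np.median(frac) == pytest.approx(0.9, abs=0.05)

    def test_equal_d_two_component_collapses_to_one(self):
        g = np.geomspace(0.01, 0.28, 40)
        curve = gen_pfg_decay(2e-10, g, 0.005, 0.1)
        one = fit_stejskal_tanner(curve, n_components=1)
        two = fit_stejskal_tanner(curve, n_components=2)
        # the fraction is degenerate; the dominant component carries the
        # single-component D and the mixture model reproduces the curve
        assert two.d_main == pytest.approx(one.d[0], rel=1e-3)
        from confobs.nmr import st_kernel

        k = st_kernel(g, 0.005, 0.1)
        model = two.i0 * (two.fractions[0] * np.exp(-two.d[0] * k)
                          + two.fractions[1] * np.exp(-two.d[1] * k))
        np.testing.assert_allclose(model, curve.intensity, rtol=1e-6)

    def test_degenerate_decay_raises(self):
        flat = DecayCurve(np.linspace(0.01, 0.2, 6), np.ones(6), kind="pfg",
                          delta=0.005, big_delta=0.1)
        with pytest.raises(FitError):
            fit_stejskal_tanner(flat)


class TestRelaxationFits:
    def test_round_trip_and_r2(self):
        curve = gen_cpmg_decay(1.2, np.geomspace(0.02, 1.2, 15))
        fit = fit_t2(curve)
        assert fit.t2 == pytest.approx(1.2, rel=1e-8)
        assert fit.r2 == 1.0 / fit.t2

    def test_constant_intensities_flagged_as_unbounded(self):
        flat = DecayCurve(np.linspace(0.01, 1, 8), np.full(8, 2.0), kind="cpmg")
        with pytest.raises(FitError):
            fit_t2(flat)

    def test_t2_invariant_to_intensity_scaling(self):
        t = np.geomspace(0.02, 1.5, 15)
        a = fit_t2(gen_cpmg_decay(0.7, t, i0=1.0, noise_sd=0.01, seed=2))
        b = fit_t2(gen_cpmg_decay(0.7, t, i0=250.0, noise_sd=0.01, seed=2))
        assert a.t2 == pytest.approx(b.t2, rel=1e-6)


class TestHydrodynamicRadius:
    def test_printed_peptide_and_complex_values(self):
        # D pairs (solute, dioxane) on the instrument's 1e-10 m^2/s scale
        assert round_rh(hydrodynamic_radius(2.162, 14.10)) == pytest.approx(
            13.82, abs=0.02)
        assert round_rh(hydrodynamic_radius(0.986, 13.61)) == pytest.approx(
            29.3, abs=0.05)

    def test_identity_ratio_returns_reference_radius(self):
        assert hydrodynamic_radius(3.0, 3.0) == pytest.approx(2.12)

    def test_scale_invariance_of_the_ratio(self):
        base = hydrodynamic_radius(2.162, 14.10)
        for scale in (1e-10, 7.0, 1e3):
            assert hydrodynamic_radius(2.162 * scale, 14.10 * scale) == pytest.approx(
                base, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            hydrodynamic_radius(0.0, 14.1)
        with pytest.raises(ValueError):
            hydrodynamic_radius(2.0, -1.0)


class TestStoichiometry:
    def test_equal_normalised_areas_give_unity(self):
        table = PeakTable(pd.DataFrame({
            "species": ["peptide", "ligand"],
            "region": ["a", "b"],
            "area": [10.0, 5.0],
            "protons_per_molecule": [2, 1],
        }))
        assert stoichiometry_from_peaks(table) == pytest.approx(1.0)

    def test_defining_relation_hand_case(self):
        # areas (8, 1) with protons (2, 1): (8/2)/(1/1) = 4
        table = PeakTable(pd.DataFrame({
            "species": ["ligand", "peptide"],
            "region": ["a", "b"],
            "area": [8.0, 1.0],
            "protons_per_molecule": [2, 1],
        }))
        assert stoichiometry_from_peaks(table) == pytest.approx(4.0)

    def test_missing_species_or_zero_area_rejected(self):
        only_pep = PeakTable(pd.DataFrame({
            "species": ["peptide"], "region": ["a"], "area": [1.0],
            "protons_per_molecule": [1]}))
        with pytest.raises(ValueError):
            stoichiometry_from_peaks(only_pep)
        zero = PeakTable(pd.DataFrame({
            "species": ["peptide", "ligand"], "region": ["a", "b"],
            "area": [0.0, 1.0], "protons_per_molecule": [1, 1]}))
        with pytest.raises(ValueError):
            stoichiometry_from_peaks(zero)


class TestSeHplc:
    def synthetic_standards(self, slope=-0.55, intercept=2.8):
        vols = np.array([2.2, 2.6, 3.0, 3.4, 3.7])
        rh = 10.0 ** (intercept + slope * vols)
        return list(zip(rh, vols)), slope, intercept

    def test_noise_free_calibration_recovers_the_line(self):
        standards, slope, intercept = self.synthetic_standards()
        model = calibrate_sehplc(standards)
        assert model.slope == pytest.approx(slope, rel=1e-10)
        assert model.intercept == pytest.approx(intercept, rel=1e-10)

    def test_query_at_a_standard_returns_its_radius(self):
        standards, _, _ = self.synthetic_standards()
        model = calibrate_sehplc(standards)
        rh, in_range = sehplc_rh(model, standards[2][1])
        assert rh == pytest.approx(standards[2][0], rel=1e-10)
        assert in_range

    def test_prediction_past_linearity_limit_is_flagged(self):
        standards, _, _ = self.synthetic_standards()
        model = calibrate_sehplc(standards)
        assert model.volume_range_ml[1] <= 3.8
        _, in_range = sehplc_rh(model, 4.0)
        assert not in_range

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValueError):
            calibrate_sehplc([(10.0, 2.0), (5.0, 3.0)])


class TestMre:
    def test_zero_signal_gives_zero_mre(self):
        out = mean_residue_ellipticity(np.zeros(5), 0.2, 0.1, 110.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_doubling_path_halves_mre(self):
        theta = np.array([50.0, -30.0, 10.0])
        a = mean_residue_ellipticity(theta, 0.2, 0.1, 110.0)
        b = mean_residue_ellipticity(theta, 0.2, 0.2, 110.0)
        np.testing.assert_allclose(b, a / 2.0)

    def test_hand_computed_value(self):
        # theta=100 mdeg, mrw=110 g/mol, c=0.2 mg/mL, l=0.1 cm
        out = mean_residue_ellipticity(np.array([100.0]), 0.2, 0.1, 110.0)
        assert out[0] == pytest.approx(100.0 * 110.0 / (10.0 * 0.1 * 0.2))
        assert out[0] == pytest.approx(55000.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            mean_residue_ellipticity(np.ones(3), 0.0, 0.1, 110.0)


def test_decay_curve_validation():
    with pytest.raises(ValueError):
        DecayCurve(np.array([1.0, 2.0, 3.0]), np.ones(3), kind="cpmg")  # too short
    with pytest.raises(ValueError):
        DecayCurve(np.array([1.0, 1.0, 2.0, 3.0]), np.ones(4), kind="cpmg")
    with pytest.raises(ValueError):
        DecayCurve(np.arange(1, 5, dtype=float), np.ones(4), kind="pfg")  # no delta
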