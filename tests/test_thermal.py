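import numpy as np
import pytest

from cpdesign.thermal import (
    DSCThermogram,
    FitError,
    MeltCurve,
    SyntheticMeltParams,
    excess_heat_capacity,
    find_peaks,
    fit_half_transition,
    half_transition_interp,
    molar_ellipticity,
    normalize_melt,
    read_melt_csv,
    simulate_cd_melt,
    simulate_dsc,
    write_melt_csv,
)

#: sloped-baseline thermogram parameters reused across DSC tests
DSC_BASELINES = dict(
    pre_slope=0.01, pre_intercept=5.0, post_slope=0.02, post_intercept=7.0,
    n_points=141,
)


class TestMolarEllipticity:
    def test_zero_signal(self):
        assert molar_ellipticity(0.0, 110.0, 1.0, 0.1) == 0.0

    def test_direct_substitution(self):
        assert molar_ellipticity(10.0, 110.0, 1.0, 0.1) == pytest.approx(11000.0)

    def test_homogeneity_in_concentration(self):
        one = molar_ellipticity(5.0, 110.0, 1.0, 0.1)
        two = molar_ellipticity(5.0, 110.0, 2.0, 0.1)
        assert two == pytest.approx(one / 2)

    @pytest.mark.parametrize("c,l", [(0.0, 0.1), (1.0, 0.0), (-1.0, 0.1)])
    def test_nonpositive_inputs_rejected(self, c, l):
        with pytest.raises(ValueError):
            molar_ellipticity(1.0, 110.0, c, l)


class TestNormalizeMelt:
    def test_minmax_arithmetic(self):
        curve = MeltCurve([10, 20, 30, 40, 50], [2, 3, 4, 5, 6])
        out = normalize_melt(curve)
        np.testing.assert_allclose(out.signal, [0, 0.25, 0.5, 0.75, 1.0])
        assert out.normalized

    def test_minmax_idempotent(self):
        curve = MeltCurve([10, 20, 30, 40, 50], [0.0, 0.1, 0.5, 0.9, 1.0])
        once = normalize_melt(curve)
        twice = normalize_melt(once)
        np.testing.assert_allclose(twice.signal, once.signal)

    def test_constant_signal_is_error(self):
        curve = MeltCurve([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])
        with pytest.raises(ValueError, match="zero range"):
            normalize_melt(curve)

    def test_baseline_fraction_recovers_generating_sigmoid(self):
        params = SyntheticMeltParams(
            t_m=60.0, dH_vH=400.0, noise_sd=0.0,
            pre_slope=-0.002, pre_intercept=1.1,
            post_slope=-0.001, post_intercept=0.15,
        )
        curve = simulate_cd_melt(params)
        frac = normalize_melt(curve, mode="baseline_fraction")
        from cpdesign.thermal import _fraction_unfolded

        f_true = _fraction_unfolded(curve.temperatures, 60.0, 400.0)
        np.testing.assert_allclose(frac.signal, f_true, atol=0.02)


class TestFitHalfTransition:
    def test_noiseless_recovery(self):
        curve = simulate_cd_melt(SyntheticMeltParams(t_m=60.0, dH_vH=300.0, noise_sd=0.0))
        fit = fit_half_transition(curve)
        assert fit.t_half == pytest.approx(60.0, abs=0.01)
        assert fit.dH_vH == pytest.approx(300.0, rel=0.01)

    def test_noisy_recovery_fixed_seed(self):
        curve = simulate_cd_melt(
            SyntheticMeltParams(t_m=60.0, dH_vH=300.0, noise_sd=0.02, seed=11)
        )
        fit = fit_half_transition(curve)
        assert fit.t_half == pytest.approx(60.0, abs=0.2)

    def test_polarity_reversal_gives_same_t_half(self):
        up = simulate_cd_melt(SyntheticMeltParams(t_m=63.0, noise_sd=0.02, seed=4))
        down = MeltCurve(up.temperatures, 1.0 - up.signal)
        assert fit_half_transition(down).t_half == pytest.approx(
            fit_half_transition(up).t_half, abs=1e-6
        )

    def test_sloped_baselines_recovered(self):
        params = SyntheticMeltParams(
            t_m=55.0, dH_vH=350.0, noise_sd=0.0,
            pre_slope=-0.003, pre_intercept=1.2,
            post_slope=-0.001, post_intercept=0.2,
        )
        fit = fit_half_transition(simulate_cd_melt(params))
        assert fit.t_half == pytest.approx(55.0, abs=0.05)
        assert fit.pre_slope == pytest.approx(-0.003, abs=5e-4)

    def test_median_recovery_over_seeded_replicates(self):
        rng = np.random.default_rng(7)
        errors = []
        for i in range(20):
            t_m = float(rng.uniform(45, 75))
            curve = simulate_cd_melt(
                SyntheticMeltParams(t_m=t_m, noise_sd=0.02, seed=500 + i)
            )
            errors.append(abs(fit_half_transition(curve).t_half - t_m))
        assert np.median(errors) < 0.2

    def test_too_few_points_is_error(self):
        curve = MeltCurve([1, 2, 3, 4, 5], [0, 0.1, 0.5, 0.9, 1.0])
        with pytest.raises(FitError):
            fit_half_transition(curve)

    def test_interp_method_agrees_with_fit(self):
        curve = simulate_cd_melt(SyntheticMeltParams(t_m=58.0, noise_sd=0.01, seed=9))
        fit = fit_half_transition(curve)
        interp = half_transition_interp(curve)
        assert interp.method == "interp"
        assert interp.t_half == pytest.approx(fit.t_half, abs=0.3)


class TestExcessHeatCapacity:
    def test_linear_thermogram_has_zero_excess(self):
        t = np.linspace(20, 90, 71)
        gram = excess_heat_capacity(DSCThermogram(t, 0.05 * t + 3.0))
        assert np.abs(gram.excess).max() < 1e-9

    def test_peak_area_matches_generating_enthalpy(self):
        params = SyntheticMeltParams(
            t_m=61.1, dH_vH=400.0, noise_sd=0.0, **DSC_BASELINES
        )
        gram = excess_heat_capacity(simulate_dsc(params))
        area = np.trapezoid(gram.excess, gram.temperatures)
        assert area == pytest.approx(400.0, rel=0.01)

    def test_invariant_to_global_linear_offset(self):
        params = SyntheticMeltParams(t_m=61.1, dH_vH=400.0, noise_sd=0.0, **DSC_BASELINES)
        gram = simulate_dsc(params)
        shifted = DSCThermogram(gram.temperatures, gram.cp + 0.3 * gram.temperatures - 7.0)
        a = excess_heat_capacity(gram).excess
        b = excess_heat_capacity(shifted).excess
        assert np.abs(a - b).max() < 1e-6 * np.abs(a).max()

    def test_overlapping_windows_rejected(self):
        t = np.linspace(20, 90, 71)
        gram = DSCThermogram(t, 0.05 * t)
        with pytest.raises(ValueError, match="overlap"):
            excess_heat_capacity(gram, windows=((20, 60), (50, 90)))

    def test_near_nonnegative_excess(self):
        params = SyntheticMeltParams(t_m=61.1, dH_vH=400.0, noise_sd=0.0, **DSC_BASELINES)
        gram = excess_heat_capacity(simulate_dsc(params))
        # small undershoot from transition tails leaking into the baseline
        # windows is tolerated up to 1e-3 of the peak height
        assert gram.excess.min() > -1e-3 * gram.excess.max()


class TestFindPeaks:
    def test_single_transition(self):
        params = SyntheticMeltParams(t_m=61.1, dH_vH=400.0, noise_sd=0.0, **DSC_BASELINES)
        peaks = find_peaks(excess_heat_capacity(simulate_dsc(params)))
        assert len(peaks) == 1
        grid = 0.5  # 141 points over 70 degC
        assert peaks[0][0] == pytest.approx(61.1, abs=grid / 2)

    def test_two_transitions_resolved(self):
        params = SyntheticMeltParams(
            transitions=((45.1, 800.0, 1.0), (51.0, 800.0, 1.0)),
            noise_sd=0.0, **DSC_BASELINES,
        )
        peaks = find_peaks(excess_heat_capacity(simulate_dsc(params)))
        assert len(peaks) == 2
        recovered = sorted(t for t, _ in peaks)
        assert recovered[0] == pytest.approx(45.1, abs=0.3)
        assert recovered[1] == pytest.approx(51.0, abs=0.3)

    def test_separated_transitions_both_found(self):
        # resolvability bound of the generator's stated transition width
        for sep in (4.5, 6.0, 10.0):
            params = SyntheticMeltParams(
                transitions=((48.0, 800.0, 1.0), (48.0 + sep, 800.0, 1.0)),
                noise_sd=0.0, **DSC_BASELINES,
            )
            peaks = find_peaks(excess_heat_capacity(simulate_dsc(params)))
            assert len(peaks) == 2, f"separation {sep}"

    def test_flat_excess_gives_no_peaks(self):
        t = np.linspace(20, 90, 71)
        gram = DSCThermogram(t, np.full(71, 3.0), excess=np.zeros(71))
        assert find_peaks(gram) == []

    def test_requires_excess(self):
        t = np.linspace(20, 90, 71)
        with pytest.raises(ValueError, match="excess"):
            find_peaks(DSCThermogram(t, np.full(71, 3.0)))


class TestSyntheticGenerator:
    def test_same_seed_identical(self):
        p = SyntheticMeltParams(t_m=60.0, seed=5)
        a, b = simulate_cd_melt(p), simulate_cd_melt(p)
        np.testing.assert_array_equal(a.signal, b.signal)
        g1, g2 = simulate_dsc(p), simulate_dsc(p)
        np.testing.assert_array_equal(g1.cp, g2.cp)

    def test_zero_noise_matches_analytic_model(self):
        from cpdesign.thermal import _fraction_unfolded

        p = SyntheticMeltParams(t_m=60.0, dH_vH=300.0, noise_sd=0.0)
        curve = simulate_cd_melt(p)
        np.testing.assert_allclose(
            curve.signal, _fraction_unfolded(curve.temperatures, 60.0, 300.0)
        )

    def test_transition_derivative_integrates_to_unity(self):
        # df/dT integrates to 1 across a wide grid; the simulated excess per
        # transition therefore integrates to dH
        from cpdesign.thermal import _dsc_excess_model

        t = np.linspace(0, 120, 2001)
        excess = _dsc_excess_model(t, ((60.0, 300.0, 1.0),))
        assert np.trapezoid(excess, t) / 300.0 == pytest.approx(1.0, abs=1e-3)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SyntheticMeltParams(noise_sd=-0.1)


class TestCurveIO:
    def test_csv_round_trip(self, tmp_path):
        curve = simulate_cd_melt(SyntheticMeltParams(seed=2))
        p = tmp_path / "melt.csv"
        write_melt_csv(curve, p)
        back = read_melt_csv(p, kind="cd")
        np.testing.assert_allclose(back.signal, curve.signal)
        np.testing.assert_allclose(back.temperatures, curve.temperatures)

    def test_header_required(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("20,0.1\n21,0.2\n")
        with pytest.raises(ValueError, match="temperature_C"):
            read_melt_csv(p)

    def test_dsc_kind(self, tmp_path):
        gram = simulate_dsc(SyntheticMeltParams(seed=2))
        p = tmp_path / "dsc.csv"
        write_melt_csv(gram, p)
        assert isinstance(read_melt_csv(p, kind="dsc"), DSCThermogram)
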