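"""CD spectral decomposition and melting-temperature extraction."""

import numpy as np
import pytest

from qdhfold import synthetic_data as S
from qdhfold.cd_analysis import (
    Baseline,
    CDSpectrum,
    MeltCurve,
    decompose_two_state,
    fit_baselines,
    melt_tm,
)


@pytest.fixture(scope="module")
def components():
    return S.form1_like_spectrum(), S.form2_like_spectrum()


class TestDecomposition:
    def test_pure_component_recovered(self, components):
        c1, c2 = components
        w1, w2, resid = decompose_two_state(c1, c1, c2)
        assert w1 == pytest.approx(1.0, abs=1e-12)
        assert w2 == pytest.approx(0.0, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_mixture_exact(self, components):
        c1, c2 = components
        mix = S.simulate_cd_mixture(0.5, c1, c2, noise_sd=0.0)
        w1, _, _ = decompose_two_state(mix, c1, c2)
        assert w1 == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("true_w1", [0.0, 0.19, 0.5, 0.81, 1.0])
    def test_exact_inverse_across_simplex(self, components, true_w1):
        c1, c2 = components
        mix = S.simulate_cd_mixture(true_w1, c1, c2, noise_sd=0.0)
        w1, w2, _ = decompose_two_state(mix, c1, c2)
        assert w1 == pytest.approx(true_w1, abs=1e-10)
        assert w1 + w2 == pytest.approx(1.0)

    def test_noisy_recovery_near_truth(self, components):
        c1, c2 = components
        mix = S.simulate_cd_mixture(0.81, c1, c2, noise_sd=0.01, seed=11)
        w1, _, _ = decompose_two_state(mix, c1, c2)
        assert 0.79 <= w1 <= 0.83

    def test_recovery_error_decreases_with_noise(self, components):
        c1, c2 = components
        errs = []
        for sd in (0.05, 0.005):
            e = [
                abs(decompose_two_state(
                    S.simulate_cd_mixture(0.7, c1, c2, sd, seed), c1, c2
                )[0] - 0.7)
                for seed in range(20)
            ]
            errs.append(np.mean(e))
        assert errs[1] < errs[0]

    def test_identical_components_rejected(self, components):
        c1, _ = components
        mix = S.simulate_cd_mixture(0.5, c1, c1, noise_sd=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            decompose_two_state(mix, c1, c1)

    def test_resampling_onto_common_support(self, components):
        c1, c2 = components
        mix = S.simulate_cd_mixture(0.81, c1, c2, noise_sd=0.0)
        coarse = CDSpectrum(c1.wavelength[::2], c1.ellipticity[::2])
        w1, _, _ = decompose_two_state(mix, coarse, c2)
        assert w1 == pytest.approx(0.81, abs=1e-3)


class TestBaselines:
    def test_linear_curve_gives_identical_baselines(self):
        t = np.arange(15.0, 96.0, 1.0)
        curve = MeltCurve(t, 0.02 * t + 1.0)
        lo, hi = fit_baselines(curve, (15, 25), (85, 95))
        for b in (lo, hi):
            assert b.slope == pytest.approx(0.02)
            assert b.intercept == pytest.approx(1.0)

    def test_flat_sigmoid_baselines(self):
        curve = S.simulate_melting_curve(
            tm=50.0, vant_hoff_dh=60.0,
            folded_baseline=Baseline(0.0, 1.0),
            unfolded_baseline=Baseline(0.0, 0.0),
        )
        lo, hi = fit_baselines(curve, (15, 25), (85, 95))
        assert lo.slope == pytest.approx(0.0, abs=1e-3)
        assert lo.intercept == pytest.approx(1.0, abs=1e-2)
        assert hi.slope == pytest.approx(0.0, abs=1e-3)
        assert hi.intercept == pytest.approx(0.0, abs=1e-2)

    def test_short_window_rejected(self):
        curve = S.simulate_melting_curve(tm=50.0)
        with pytest.raises(ValueError, match="at least 3"):
            fit_baselines(curve, (15, 16), (85, 95))

    def test_overlapping_windows_rejected(self):
        curve = S.simulate_melting_curve(tm=50.0)
        with pytest.raises(ValueError, match="overlap"):
            fit_baselines(curve, (15, 60), (55, 95))


class TestMeltTm:
    def test_known_tm_recovered(self):
        for tm in (65.0, 67.0):
            curve = S.simulate_melting_curve(tm=tm)
            fit = melt_tm(curve, fit_baselines(curve, (15, 25), (85, 95)))
            assert fit.tm == pytest.approx(tm, abs=0.2)

    def test_symmetric_sigmoid_centered(self):
        curve = S.simulate_melting_curve(
            tm=50.0,
            folded_baseline=Baseline(0.0, 1.0),
            unfolded_baseline=Baseline(0.0, 0.0),
        )
        fit = melt_tm(curve, fit_baselines(curve, (15, 25), (85, 95)))
        assert fit.tm == pytest.approx(50.0, abs=0.05)

    def test_affine_rescaling_invariance(self):
        curve = S.simulate_melting_curve(tm=62.0)
        scaled = MeltCurve(curve.temperature, 3.7 * curve.ellipticity - 11.0)
        tm0 = melt_tm(curve, fit_baselines(curve, (15, 25), (85, 95))).tm
        tm1 = melt_tm(scaled, fit_baselines(scaled, (15, 25), (85, 95))).tm
        assert tm1 == pytest.approx(tm0, abs=1e-9)

    def test_theta_clipped_to_unit_interval(self):
        curve = S.simulate_melting_curve(tm=55.0, noise_sd=0.01, seed=3)
        fit = melt_tm(curve, fit_baselines(curve, (15, 25), (85, 95)))
        assert np.all(fit.theta >= 0.0) and np.all(fit.theta <= 1.0)

    def test_incomplete_transition_rejected(self):
        # a curve that stays fully folded never crosses theta = 0.5
        t = np.arange(15.0, 96.0, 1.0)
        curve = MeltCurve(t, np.ones_like(t))
        baselines = (Baseline(0.0, 1.0), Baseline(0.0, 0.0))
        with pytest.raises(ValueError, match="never crosses"):
            melt_tm(curve, baselines)

    def test_folding_unfolding_hysteresis_below_one_degree(self):
        # folding and unfolding replicates from the same two-state model
        fold = S.simulate_melting_curve(tm=65.0, noise_sd=0.004, seed=1)
        unfold = S.simulate_melting_curve(tm=65.0, noise_sd=0.004, seed=2)
        tms = [
            melt_tm(c, fit_baselines(c, (15, 25), (85, 95))).tm
            for c in (fold, unfold)
        ]
        assert abs(tms[0] - tms[1]) < 1.0


class TestGenerators:
    def test_theta_half_at_tm(self):
        assert S.two_state_theta(np.array([65.0]), 65.0, 50.0)[0] == pytest.approx(0.5)

    def test_transition_width_narrows_with_dh(self):
        t = np.arange(15.0, 96.0, 0.5)

        def width(dh):
            theta = S.two_state_theta(t, 55.0, dh)
            inside = t[(theta < 0.9) & (theta > 0.1)]
            return inside[-1] - inside[0]

        assert width(100.0) < width(40.0)

    def test_seeded_generators_reproducible(self):
        c1, c2 = S.form1_like_spectrum(), S.form2_like_spectrum()
        a = S.simulate_cd_mixture(0.6, c1, c2, 0.02, seed=5)
        b = S.simulate_cd_mixture(0.6, c1, c2, 0.02, seed=5)
        assert np.array_equal(a.ellipticity, b.ellipticity)
        m1 = S.simulate_melting_curve(tm=60.0, noise_sd=0.01, seed=9)
        m2 = S.simulate_melting_curve(tm=60.0, noise_sd=0.01, seed=9)
        assert np.array_equal(m1.ellipticity, m2.ellipticity)

    def test_component_signatures(self):
        c1, c2 = S.form1_like_spectrum(), S.form2_like_spectrum()
        w = c1.wavelength
        assert w[np.argmax(c1.ellipticity)] == pytest.approx(265.0, abs=3)
        assert w[np.argmax(c2.ellipticity)] == pytest.approx(290.0, abs=3)
        assert w[np.argmin(c2.ellipticity)] == pytest.approx(255.0, abs=3)
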