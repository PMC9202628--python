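import numpy as np
import pytest

from aquaforecast.timeseries import UniformSeries
from aquaforecast.vmd import VMDConfig
from aquaforecast.wavelet_denoise import (ThresholdRule, ThresholdSpec,
                                          apply_threshold, denoise_component,
                                          joint_denoise, pearson_correlation,
                                          route_components, universal_threshold)
from aquaforecast.wavelet_denoise import _packet_decompose, _packet_reconstruct

from conftest import make_noisy_trend_tone


class TestPearson:
    def test_self_correlation_one(self):
        x = np.random.default_rng(0).standard_normal(50)
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_correlation(np.array([1.0, 2, 3]), np.array([1.0, 2, 4])) \
            == pytest.approx(0.9820, abs=1e-4)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestRouting:
    def test_published_dissolved_oxygen_pattern(self):
        """Correlations (0.662, 0.726, 0.369) with cutoff 0.5 flag only the third."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        modes = []
        for target in (0.662, 0.726, 0.369):
            noise = rng.standard_normal(4000)
            # mix to achieve the target correlation exactly in expectation
            m = target * (x - x.mean()) / x.std() + np.sqrt(1 - target**2) * noise
            modes.append(m)
        keep, denoise, corrs = route_components(np.array(modes), x)
        assert keep == [0, 1] and denoise == [2]

    def test_all_kept_when_above_cutoff(self):
        x = np.sin(np.linspace(0, 20, 400))
        modes = np.array([x, 0.5 * x])
        keep, denoise, _ = route_components(modes, x)
        assert denoise == []

    def test_anticorrelated_mode_kept(self):
        """Routing uses |r|: a strongly anti-correlated mode is informative."""
        x = np.sin(np.linspace(0, 20, 400))
        keep, denoise, corrs = route_components(np.array([-x]), x)
        assert keep == [0]
        assert corrs[0] == pytest.approx(-1.0)


class TestUniversalThreshold:
    def test_all_zero_coefficients(self):
        assert universal_threshold(np.zeros(8), 8) == 0.0

    def test_hand_value(self):
        expected = (1.0 / 0.6745) * np.sqrt(2.0 * np.log(4.0))  # 2.468657...
        lam = universal_threshold(np.array([1.0, -1.0, 1.0, -1.0]), 4)
        assert lam == pytest.approx(expected, abs=1e-12)
        assert lam == pytest.approx(2.4687, abs=1e-4)

    def test_monotone_in_signal_length(self):
        w = np.array([1.0, -2.0, 0.5])
        lams = [universal_threshold(w, n) for n in (4, 16, 256, 4096)]
        assert np.all(np.diff(lams) > 0)

    def test_empty_coefficients_error(self):
        with pytest.raises(ValueError):
            universal_threshold(np.array([]), 4)


class TestThresholdRules:
    @pytest.mark.parametrize("s,expected", [(2.0, 1.0), (-2.0, -1.0), (0.5, 0.0)])
    def test_soft_branches(self, s, expected):
        spec = ThresholdSpec(rule=ThresholdRule.SOFT)
        out = apply_threshold({"d": np.array([s])}, 1.0, spec)
        assert out["d"][0] == pytest.approx(expected)

    def test_hard_keeps_survivors_unchanged(self):
        spec = ThresholdSpec(rule=ThresholdRule.HARD)
        out = apply_threshold({"d": np.array([2.0, 0.5])}, 1.0, spec)
        np.testing.assert_allclose(out["d"], [2.0, 0.0])

    def test_compromise_is_convex_combination(self):
        spec = ThresholdSpec(rule=ThresholdRule.COMPROMISE, compromise_weight=0.5)
        out = apply_threshold({"d": np.array([2.0])}, 1.0, spec)
        assert out["d"][0] == pytest.approx(1.5)

    def test_soft_is_shrinkage_hard_is_idempotent(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal(200)
        soft = apply_threshold({"d": c}, 0.7, ThresholdSpec(rule=ThresholdRule.SOFT))["d"]
        assert np.all(np.abs(soft) <= np.abs(c) + 1e-15)
        hard_spec = ThresholdSpec(rule=ThresholdRule.HARD)
        once = apply_threshold({"d": c}, 0.7, hard_spec)["d"]
        twice = apply_threshold({"d": once}, 0.7, hard_spec)["d"]
        np.testing.assert_array_equal(once, twice)

    def test_energy_non_increase_all_rules(self):
        rng = np.random.default_rng(2)
        c = rng.standard_normal(500)
        for rule in ThresholdRule:
            out = apply_threshold({"d": c}, 0.5, ThresholdSpec(rule=rule))["d"]
            assert np.sum(out ** 2) <= np.sum(c ** 2)

    def test_approximation_node_untouched(self):
        spec = ThresholdSpec(levels=2, rule=ThresholdRule.SOFT)
        coeffs = {"aa": np.array([5.0, -5.0]), "ad": np.array([5.0, -5.0])}
        out = apply_threshold(coeffs, 10.0, spec)
        np.testing.assert_array_equal(out["aa"], coeffs["aa"])
        np.testing.assert_allclose(out["ad"], 0.0)


class TestDenoiseComponent:
    def test_zero_series_stays_zero(self):
        out = denoise_component(np.zeros(64))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_perfect_reconstruction_with_zero_threshold(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(300)
        spec = ThresholdSpec()
        coeffs = _packet_decompose(x, spec)
        rec = _packet_reconstruct(apply_threshold(coeffs, 0.0, spec), spec, x.size)
        assert np.max(np.abs(rec - x)) / np.max(np.abs(x)) < 1e-8

    def test_smooth_sinusoid_barely_altered(self):
        t = np.arange(1024.0)
        clean = np.sin(2 * np.pi * 0.02 * t)
        out = denoise_component(clean)
        rmse = np.sqrt(np.mean((out - clean) ** 2))
        assert rmse < 0.02 * np.sqrt(np.mean(clean ** 2))

    def test_snr_gain_on_noisy_sinusoid(self):
        """At 5 dB input SNR the output gains >= 3 dB against the clean truth."""
        t = np.arange(1024.0)
        clean = np.sin(2 * np.pi * 0.02 * t)
        sd = np.sqrt(np.mean(clean ** 2) / 10 ** 0.5)  # 5 dB
        noisy = clean + sd * np.random.default_rng(3).standard_normal(1024)
        out = denoise_component(noisy)
        def snr(sig):
            return 10 * np.log10(np.mean(clean ** 2) / np.mean((sig - clean) ** 2))
        assert snr(out) >= snr(noisy) + 3.0

    def test_output_length_matches_input(self):
        x = np.random.default_rng(4).standard_normal(101)
        assert denoise_component(x).size == 101

    def test_too_short_for_levels_errors(self):
        with pytest.raises(ValueError):
            denoise_component(np.arange(4.0), ThresholdSpec(levels=3))


class TestJointDenoise:
    def test_improves_rmse_in_most_seeds(self, trend_tone_fixture):
        clean = trend_tone_fixture
        wins = 0
        for seed in range(5):
            noisy = make_noisy_trend_tone(clean, seed)
            out, _ = joint_denoise(noisy, VMDConfig(k=3, alpha=2000))
            r_in = np.sqrt(np.mean((noisy.values - clean) ** 2))
            r_out = np.sqrt(np.mean((out.values - clean) ** 2))
            wins += r_out < r_in
        assert wins >= 4

    def test_output_length_preserved(self, trend_tone_fixture):
        noisy = make_noisy_trend_tone(trend_tone_fixture, 0)
        out, _ = joint_denoise(noisy, VMDConfig(k=3, alpha=2000))
        assert len(out) == len(noisy)

    def test_no_flagged_components_equals_vmd_reconstruction(self):
        """With cutoff 0 nothing is denoised: output is the plain mode sum."""
        from aquaforecast.vmd import reconstruct, vmd_decompose
        t = np.arange(512.0)
        x = UniformSeries("x", np.sin(2 * np.pi * 0.02 * t) + 0.3 * np.sin(2 * np.pi * 0.2 * t))
        cfg = VMDConfig(k=2, alpha=2000)
        out, art = joint_denoise(x, cfg, cutoff=0.0)
        assert art["denoised"] == []
        np.testing.assert_allclose(out.values, reconstruct(vmd_decompose(x, cfg)))
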