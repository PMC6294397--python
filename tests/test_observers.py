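import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import classim as ci
from classim.observers import _mean_dprime


class TestDOGFilter:
    def test_unit_energy_and_symmetry(self):
        f = ci.dog_filter()
        assert np.sum(f ** 2) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(f, f[::-1])

    def test_mexican_hat_shape(self):
        f = ci.dog_filter()
        c = len(f) // 2
        assert f[c] > 0
        assert f[c - 2] < 0 and f[c + 2] < 0  # inhibitory surround

    def test_even_support_rejected(self):
        with pytest.raises(ValueError):
            ci.DOGSpec(support=24)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            ci.DOGSpec(sigma1=30.0, sigma2=20.0)


class TestFrontend:
    def test_zero_stimulus_maps_to_zero(self):
        f = ci.dog_filter()
        assert np.all(ci.frontend(np.zeros(13), f) == 0)

    def test_impulse_response_is_filter_slice(self):
        f = ci.dog_filter()
        s = np.zeros(13)
        s[6] = 1.0
        out = ci.frontend(s, f)
        expect = f[len(f) // 2 - 6:len(f) // 2 + 7]
        assert np.allclose(out, expect)

    @pytest.mark.parametrize("a", [-2.0, 0.5])
    def test_homogeneity(self, a, rng):
        f = ci.dog_filter()
        s = rng.normal(size=13)
        assert np.allclose(ci.frontend(a * s, f), a * ci.frontend(s, f))


class TestGainControl:
    def test_zero_input_passes_through(self):
        assert np.all(ci.gain_control_linear(np.zeros(13)) == 0)
        assert np.all(ci.gain_control_nonlinear(np.zeros(13)) == 0)

    def test_linear_semisaturation_constant(self, rng):
        # zero-sum input: division by exactly 10
        b = rng.normal(size=13)
        b -= b.mean()
        assert np.allclose(ci.gain_control_linear(b), b / 10.0)

    def test_linear_output_vanishes_at_high_drive(self):
        shape = np.ones(13)
        small = ci.gain_control_linear(1e6 * shape)
        assert np.all(np.abs(small) < 1e-4)

    @given(st.floats(min_value=0.01, max_value=1e6))
    @settings(max_examples=30, deadline=None)
    def test_nonlinear_sum_saturates_below_one(self, scale):
        b = scale * np.ones(13) / 13.0
        out = ci.gain_control_nonlinear(b)
        total = out.sum()
        assert 0 <= total < 1
        assert total == pytest.approx(scale / (0.4 + scale), rel=1e-9)

    def test_nonlinear_rejects_negative_input(self):
        with pytest.raises(ValueError):
            ci.gain_control_nonlinear(np.array([1.0, -0.1, 0.0]))


class TestDecisionVariables:
    def test_template_obeys_superposition(self, rng):
        cfg = ci.ObserverConfig.for_variant(1, noise_sd=0.0)
        g = np.random.default_rng(0)
        for _ in range(5):
            s1, s2 = g.normal(size=(2, 13))
            r1 = ci.decision_variable(s1, cfg, g)
            r2 = ci.decision_variable(s2, cfg, g)
            r12 = ci.decision_variable(s1 + s2, cfg, g)
            assert r12 == pytest.approx(r1 + r2, rel=1e-9, abs=1e-12)

    def test_energy_is_polarity_blind(self, rng):
        cfg = ci.ObserverConfig.for_variant(2, noise_sd=0.0)
        g = np.random.default_rng(1)
        s = g.normal(size=13)
        assert ci.decision_variable(s, cfg, g) == pytest.approx(
            ci.decision_variable(-s, cfg, g), rel=1e-12)

    def test_max_window_widens_as_contrast_drops(self):
        cfg = ci.ObserverConfig(variant="max")
        widths = [cfg.max_sigma_w(c) for c in (4, 3, 2, 1)]
        assert widths == [40.0, 80.0, 120.0, 160.0]
        w_low = ci.readout_weights(cfg, 13, 6, contrast_level=1)
        w_high = ci.readout_weights(cfg, 13, 6, contrast_level=4)
        assert np.all(w_low >= w_high)  # broader window at low contrast

    def test_max_requires_contrast_level(self):
        cfg = ci.ObserverConfig(variant="max")
        with pytest.raises(ValueError):
            ci.decision_variables(np.zeros((1, 13)), cfg,
                                  np.random.default_rng(0))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ci.ObserverConfig(variant="quadrature")


class TestRespond:
    def test_tie_goes_to_nontarget(self):
        cond = ci.ConditionSpec(task="bright")
        tr = ci.make_trial(cond, np.random.default_rng(2))
        tr.n1 = tr.n0.copy()
        tr.t1 = np.zeros(13)  # identical stimuli -> r1 - r0 = 0
        cfg = ci.ObserverConfig.for_variant(1, noise_sd=0.0)
        rec = ci.respond(tr, cfg, np.random.default_rng(3))
        assert not rec.chose_target and not rec.correct

    def test_noiseless_high_snr_always_correct(self, rng):
        cond = ci.ConditionSpec(task="bright", contrast_level=1, snr_level=4)
        cfg = ci.ObserverConfig.for_variant(1, noise_sd=0.0)
        batch = ci.sample_stimulus_batch(
            replace(cond, snr_level=4), 200, rng)
        batch.t1_center = batch.t1_center * 100  # SNR >> 1
        assert np.all(ci.respond_batch(batch, cfg, rng))

    def test_huge_intrinsic_noise_drives_pc_to_chance(self, rng):
        cond = ci.ConditionSpec(task="bright", contrast_level=4, snr_level=4)
        cfg = ci.ObserverConfig.for_variant(1, noise_sd=1e9)
        batch = ci.sample_stimulus_batch(cond, 10000, rng)
        pc = np.mean(ci.respond_batch(batch, cfg, rng))
        assert pc == pytest.approx(0.5, abs=0.02)

    def test_fixed_seed_bit_reproducible(self, template_config):
        cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=2)
        runs = []
        for _ in range(2):
            g = np.random.default_rng(99)
            batch, correct = ci.simulate_condition(cond, 300,
                                                   template_config, g)
            runs.append((batch.n0.copy(), correct.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])


class TestIdealObserver:
    def test_mixed_task_unsupported(self, rng):
        cond = ci.ConditionSpec(task="mixed")
        with pytest.raises(ValueError):
            ci.ideal_respond(ci.make_trial(cond, rng))

    def test_equivalent_to_center_bar_comparison(self, rng):
        cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=2)
        batch = ci.sample_stimulus_batch(cond, 500, rng)
        correct = ci.ideal_respond_batch(batch)
        manual = (batch.s1[:, 6] - batch.s0[:, 6]) > 0
        assert np.array_equal(correct, manual)

    def test_polarity_noiseless_always_correct(self):
        cond = ci.ConditionSpec(task="polarity", contrast_level=1, snr_level=1)
        t0, t1 = ci.target_pair(cond)
        tr = ci.Trial(n0=np.zeros(13), n1=np.zeros(13), t0=t0, t1=t1,
                      condition=cond)
        assert ci.ideal_respond(tr).correct


class TestCalibration:
    def test_recheck_mean_dprime_near_target(self, max_config):
        # the MAX observer's noiseless ceiling clears the target, so its
        # calibrated mean d' should sit at ~1
        d = _mean_dprime(max_config, ci.full_grid(), 2000,
                         np.random.SeedSequence(7))
        assert d == pytest.approx(1.0, abs=0.12)

    def test_low_ceiling_capped_with_warning(self):
        cfg = ci.ObserverConfig.for_variant(1)
        with pytest.warns(UserWarning, match="capping"):
            sd = ci.calibrate_noise_sd(cfg, rng=np.random.default_rng(0),
                                       n_trials_per_condition=600)
        assert sd > 0

    def test_low_ceiling_strict_mode_raises(self):
        cfg = ci.ObserverConfig.for_variant(1)
        with pytest.raises(RuntimeError, match="calibration failure"):
            ci.calibrate_noise_sd(cfg, rng=np.random.default_rng(0),
                                  n_trials_per_condition=600,
                                  on_low_ceiling="raise")

    def test_doubling_stimulus_amplitude_raises_dprime(self, template_config,
                                                       rng):
        cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=2)
        batch = ci.sample_stimulus_batch(cond, 8000, rng)
        pc1 = np.mean(ci.respond_batch(batch, template_config, rng))
        batch.n0 *= 2; batch.n1 *= 2
        batch.t0_center = batch.t0_center * 2
        batch.t1_center = batch.t1_center * 2
        pc2 = np.mean(ci.respond_batch(batch, template_config, rng))
        assert pc2 > pc1  # intrinsic noise relatively weaker


class TestDoublePassSimulation:
    def test_deterministic_observer_perfectly_consistent(self, rng):
        cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=1)
        cfg = ci.ObserverConfig.for_variant(1, noise_sd=0.0)
        c1, c2 = ci.simulate_double_pass_pairs(cond, 400, cfg, rng)
        assert np.array_equal(c1, c2)

    def test_noise_dominated_observer_agrees_at_chance(self, rng):
        cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=1)
        cfg = ci.ObserverConfig.for_variant(1, noise_sd=1e9)
        c1, c2 = ci.simulate_double_pass_pairs(cond, 10000, cfg, rng)
        assert np.mean(c1 == c2) == pytest.approx(0.5, abs=0.02)


class TestConfigSerialization:
    def test_json_round_trip(self, tmp_path):
        cfg = ci.ObserverConfig.for_variant(5, noise_sd=0.37, seed=3)
        path = tmp_path / "observer.json"
        cfg.to_json(path)
        assert ci.ObserverConfig.from_json(path) == cfg
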