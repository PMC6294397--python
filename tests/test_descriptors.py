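import numpy as np
import pytest

import classim as ci
from classim.descriptors import rms, rms_star


def _decoupled_cn(m, pc, sigma, rng, n_bars=13):
    n0 = rng.normal(0, sigma, (m, n_bars))
    n1 = rng.normal(0, sigma, (m, n_bars))
    correct = rng.random(m) < pc
    return ci.classify_noise(n0, n1, correct, sigma)


def _simulated_cn(config, cond, m, rng):
    batch, correct = ci.simulate_condition(cond, m, config, rng)
    return ci.classify_noise(batch.n0, batch.n1, correct, cond.sigma_N)


class TestClassification:
    def test_two_samples_per_trial_split_by_outcome(self, rng):
        cn = _decoupled_cn(500, 0.7, 1.0, rng)
        counts = cn.counts
        assert counts[(1, 1)] == counts[(0, 1)]
        assert counts[(1, 0)] == counts[(0, 0)]
        assert sum(counts.values()) == 2 * cn.m
        assert counts[(1, 1)] / cn.m == pytest.approx(cn.pc)

    def test_all_correct_observer_leaves_error_bins_empty(self, rng):
        n0 = rng.normal(size=(50, 13))
        n1 = rng.normal(size=(50, 13))
        cn = ci.classify_noise(n0, n1, np.ones(50, bool), 1.0)
        assert cn.n10.shape[0] == 0 and cn.n00.shape[0] == 0
        with pytest.raises(ValueError, match="bin"):
            ci.first_order(cn)

    def test_misaligned_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            ci.classify_noise(rng.normal(size=(10, 13)),
                              rng.normal(size=(9, 13)),
                              np.ones(10, bool), 1.0)


class TestFirstOrder:
    def test_template_observer_image_peaks_at_target_bar(self, template_config,
                                                         rng):
        cond = ci.ConditionSpec(task="bright", contrast_level=3, snr_level=3)
        cn = _simulated_cn(template_config, cond, 20000, rng)
        h, h1, h0 = ci.first_order(cn)
        assert np.argmax(h) == cond.center_index
        # linear template: target-present and target-absent components match
        assert np.corrcoef(h1, h0)[0, 1] > 0.8

    def test_energy_observer_target_absent_image_is_flat(self, energy_config,
                                                         rng):
        """Polarity-invariant processing yields no phase-locked
        target-absent modulation, while the power-domain descriptor of
        the same samples is strongly modulated."""
        cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=2)
        cn = _simulated_cn(energy_config, cond, 30000, rng)
        _, _, h0 = ci.first_order(cn)
        null = rms_star(1, cn.m, cn.pc, cn.sigma_N, "component")
        assert rms(h0) < 3.0 * null  # within noise of zero

        _, _, p0 = ci.first_order_power(cn)
        null_p = [rms(ci.first_order_power(ci.decouple(cn, rng))[2])
                  for _ in range(30)]
        assert rms(p0) > np.percentile(null_p, 95) * 2

    def test_power_descriptor_can_be_negative(self, rng):
        # power profiles are positive but the +/- bin combination is not
        cn = _decoupled_cn(2000, 0.6, 1.0, rng)
        p, _, _ = ci.first_order_power(cn)
        assert p.shape == (7,)
        assert np.any(p < 0)


class TestSecondOrder:
    def test_symmetry(self, rng):
        H = ci.second_order(_decoupled_cn(400, 0.6, 1.0, rng))
        assert np.allclose(H, H.T)

    def test_energy_observer_has_positive_diagonal_drive(self, energy_config,
                                                         rng):
        cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=2)
        cn = _simulated_cn(energy_config, cond, 30000, rng)
        ds = ci.descriptor_set(cn)
        assert ds.lambda2 > 0.5
        assert np.mean(np.diag(ds.H)) > 0

    def test_tiny_bins_rejected(self, rng):
        cn = _decoupled_cn(3, 0.5, 1.0, rng)
        if min(cn.counts.values()) < 2:
            with pytest.raises(ValueError):
                ci.second_order(cn)


class TestExpectedRms:
    def test_closed_form_matches_decoupled_oracle(self, rng):
        """The analytic RMS* (k = sqrt(2/(m pc (1-pc)))) is the root of
        the expected mean square of a decoupled descriptor.  Pooling
        squared RMS values over 200 Monte-Carlo runs removes the small
        finite-entry Jensen bias of the per-run RMS (E[RMS] is ~2-3%
        below RMS* for a 13-entry region) and must match within 3% in
        both regimes, for the full h, its components, and both H
        regions."""
        g = np.random.default_rng(987654321)  # independent of suite order
        for m, pc, reps in [(1000, 0.6, 500), (10000, 0.75, 200)]:
            r1, r1c, r2d, r2o = [], [], [], []
            for _ in range(reps):
                cn = _decoupled_cn(m, pc, 2.0, g)
                h, h1, _ = ci.first_order(cn)
                H = ci.second_order(cn)
                r1.append(rms(h))
                r1c.append(rms(h1))
                r2d.append(rms(np.diag(H)))
                r2o.append(rms(H[~np.eye(13, dtype=bool)]))

            def pooled(values):
                return np.sqrt(np.mean(np.square(values)))

            assert pooled(r1) / rms_star(1, m, pc, 2.0, "full") == \
                pytest.approx(1.0, abs=0.03)
            assert pooled(r1c) / rms_star(1, m, pc, 2.0, "component") == \
                pytest.approx(1.0, abs=0.03)
            assert pooled(r2d) / rms_star(2, m, pc, 2.0, "diagonal") == \
                pytest.approx(1.0, abs=0.03)
            assert pooled(r2o) / rms_star(2, m, pc, 2.0, "offdiagonal") == \
                pytest.approx(1.0, abs=0.03)
            # per-run mean RMS carries only the small Jensen offset
            assert np.mean(r2d) / rms_star(2, m, pc, 2.0, "diagonal") == \
                pytest.approx(0.98, abs=0.02)

    def test_scaling_in_sigma(self):
        assert rms_star(1, 100, 0.6, 4.0) == pytest.approx(
            4 * rms_star(1, 100, 0.6, 1.0))
        assert rms_star(2, 100, 0.6, 4.0) == pytest.approx(
            16 * rms_star(2, 100, 0.6, 1.0))

    def test_degenerate_pc_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                rms_star(1, 100, bad, 1.0)


class TestDrive:
    def test_log_identities(self):
        region = np.full(13, 2.0)
        lam = ci.drive(region, 2.0)
        assert lam == pytest.approx(0.0)
        assert ci.drive(2 * region, 2.0) == pytest.approx(np.log(2))

    def test_decoupled_drive_is_null(self, rng):
        cn = _decoupled_cn(10000, 0.7, 1.5, rng)
        ds = ci.descriptor_set(cn)
        # single-estimate scatter is ~0.2 (order 1) / ~0.06 (order 2)
        assert abs(ds.lambda1) < 0.6
        assert abs(ds.lambda2) < 0.25


class TestDecoupling:
    def test_shuffle_preserves_pc_exactly(self, rng):
        cn = _decoupled_cn(999, 0.65, 1.0, rng)
        assert ci.decouple(cn, rng).pc == cn.pc

    def test_null_sd_stable_across_shuffle_sets(self, template_config, rng):
        cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=2)
        cn = _simulated_cn(template_config, cond, 4000, rng)
        sds = [ci.null_drives(cn, 60, rng)["lambda1"].std() for _ in range(2)]
        assert sds[0] == pytest.approx(sds[1], rel=0.35)


class TestEigenDecomposition:
    def test_reconstruction_identity(self, rng):
        cn = _decoupled_cn(2000, 0.6, 1.0, rng)
        H = ci.second_order(cn)
        ed = ci.eigendecompose(H)
        rebuilt = ed.eigenvectors @ np.diag(ed.eigenvalues) @ ed.eigenvectors.T
        assert np.allclose(rebuilt, H, atol=1e-10)
        assert np.allclose(ed.eigenvectors.T @ ed.eigenvectors, np.eye(13),
                           atol=1e-10)

    def test_asymmetric_input_rejected(self, rng):
        with pytest.raises(ValueError):
            ci.eigendecompose(rng.normal(size=(13, 13)))

    def test_decoupled_process_rarely_significant(self):
        """At a 3x pooled-null-SD band, a decoupled process should show
        no significant eigenvalues in the vast majority of runs."""
        g = np.random.default_rng(24601)
        clean = 0
        runs = 40
        for _ in range(runs):
            cn = _decoupled_cn(3000, 0.7, 1.0, g)
            H = ci.second_order(cn)
            null = ci.null_second_order(cn, 12, g)
            ed = ci.eigendecompose(H, null_H=null)
            if ed.significant_pos == 0 and ed.significant_neg == 0:
                clean += 1
        assert clean >= int(0.9 * runs)

    def test_few_shuffles_warns(self, rng):
        cn = _decoupled_cn(500, 0.6, 1.0, rng)
        H = ci.second_order(cn)
        with pytest.warns(UserWarning, match="fewer than 10"):
            ci.eigendecompose(H, null_H=ci.null_second_order(cn, 5, rng))


class TestSerialization:
    def test_descriptor_set_json_round_trip(self, rng, tmp_path):
        cn = _decoupled_cn(500, 0.6, 1.0, rng)
        ds = ci.descriptor_set(cn)
        path = tmp_path / "ds.json"
        ds.to_json(path)
        back = ci.DescriptorSet.from_json(path)
        assert np.allclose(back.h, ds.h)
        assert np.allclose(back.H, ds.H)
        assert back.lambda2 == ds.lambda2
        ds.export_csv(tmp_path / "h.csv", tmp_path / "H.csv")
        assert (tmp_path / "h.csv").exists()


class TestLinearInvariance:
    def test_descriptors_ignore_target_amplitude_for_linear_observer(self,
                                                                     rng):
        """For a noiseless linear observer the descriptors are computed
        from noise alone: rescaling the (constant) target leaves the
        response classification rule's dependence on noise unchanged
        except through pc, and h stays proportional to the template."""
        cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=2)
        cfg = ci.ObserverConfig.for_variant(1, noise_sd=0.9)
        cn = _simulated_cn(cfg, cond, 30000, rng)
        h, _, _ = ci.first_order(cn)
        f = ci.dog_filter(cfg.dog)
        # effective template = read-out-weighted filter; compare shapes
        from classim.observers import frontend, readout_weights
        w = readout_weights(cfg, 13, 6)
        g = frontend(np.eye(13), f).T @ w
        assert np.corrcoef(h, g)[0, 1] > 0.95
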