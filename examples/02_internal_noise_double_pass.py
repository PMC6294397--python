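"""Double-pass internal-noise estimation.

Simulates a calibrated template-matcher observer on double-pass blocks
(the second 25 trials of each 50-trial block repeat the first 25 in
permuted order), summarizes response consistency (pa) and accuracy (pc),
and inverts the 2-parameter signal-detection model to recover d'_in and
the internal-to-external noise ratio N_int.
"""

import warnings

import numpy as np

import classim as ci

warnings.filterwarnings("ignore", message=".*capping the calibration.*")
rng = np.random.default_rng(2)

config = ci.calibrated(ci.ObserverConfig.for_variant(1), rng=rng)
print(f"calibrated intrinsic-noise SD: {config.noise_sd:.3f}")

print(f"\n{'contrast':>8} {'pc':>7} {'pa':>7} {'d_in':>7} {'N_int':>7} "
      f"{'plausible':>9}")
for c in (1, 2, 3, 4):
    cond = ci.ConditionSpec(task="bright", contrast_level=c, snr_level=2)
    c1, c2 = ci.simulate_double_pass_pairs(cond, 2000, config, rng)
    summary = ci.summarize_pair_arrays(c1, c2)
    est = ci.estimate_internal_noise(summary)
    print(f"{c:>8} {summary.pc:>7.3f} {summary.pa:>7.3f} "
          f"{est.dprime_in:>7.3f} {est.N_int:>7.3f} {str(est.plausible):>9}")

print("\nWith a fixed late additive noise source, the external-noise drive")
print("grows with contrast, so the internal/external ratio N_int falls as")
print("contrast rises - response agreement pa climbs correspondingly.")
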