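"""Contrast-driven retuning in the two-branch (hybrid) observer.

Runs the hybrid model (linear branch plus gain-controlled energy branch,
variant #4) over the full 4x4 contrast x SNR grid, then prints the
contrast/SNR dependence (Pearson r) and separability of the key metric
surfaces.  The hybrid reproduces the qualitative pattern of interest:
as contrast rises, tuning sharpness and estimated internal noise fall
while the linearity index rises (divisive gain control silences the
energy branch at high contrast).
"""

import warnings

import numpy as np

import classim as ci

warnings.filterwarnings("ignore", message=".*capping the calibration.*")
rng = np.random.default_rng(4)

config = ci.calibrated(ci.ObserverConfig.for_variant(4), rng=rng)
grid = ci.run_grid(config, n_trials_per_condition=60000,
                   n_doublepass_pairs=500, rng=rng)

print("metric dependence (Pearson r against level index) and separability:")
print(f"{'metric':>16} {'contrast dep':>13} {'snr dep':>9} {'SVD index':>10}")
for name in ("sharpness", "internal_noise", "linearity", "dprime",
             "lambda2"):
    dep = grid.dependence[name]
    sep = grid.separability[name]["svd_index"]
    print(f"{name:>16} {dep['contrast']:>13.3f} {dep['snr']:>9.3f} "
          f"{sep:>10.3f}")

l2 = grid.surfaces["lambda2"].values.mean(axis=0)
print("\nsecond-order drive lambda2, averaged over SNR, by contrast level:")
print("  " + "  ".join(f"{v:+.3f}" for v in l2))
print("\nThe negative contrast dependence of sharpness and internal noise,")
print("with a positive dependence of the linearity index (lambda2 fading")
print("from positive to ~0), is the hybrid model's signature pattern.")
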