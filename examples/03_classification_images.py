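"""Classification images and drives for linear vs energy observers.

Runs the template matcher (variant #1) and the energy model (variant #2)
on the same task, computes first- and second-order descriptors from the
classified noise samples, and prints the drive metrics.  The two
architectures separate cleanly: the template has matched target-present/
absent components and no second-order structure; the energy model has a
flat target-absent image but a strongly modulated second-order
descriptor.

The aggregate nonlinearity index contains a sign(lambda2) gate, so for a
linear observer (whose lambda2 fluctuates around 0) it swings between
large positive and negative values from run to run and is only
meaningful on average - it is therefore reported as mean +- SD over 10
independent runs.
"""

import warnings

import numpy as np

import classim as ci

warnings.filterwarnings("ignore", message=".*capping the calibration.*")
rng = np.random.default_rng(3)
cond = ci.ConditionSpec(task="bright", contrast_level=2, snr_level=2)

for name, variant in (("template matcher (variant 1)", 1),
                      ("energy model (variant 2)", 2)):
    config = ci.calibrated(ci.ObserverConfig.for_variant(variant), rng=rng)
    aggs = []
    for run in range(10):
        batch, correct = ci.simulate_condition(cond, 30000, config, rng)
        cn = ci.classify_noise(batch.n0, batch.n1, correct, cond.sigma_N)
        ds = ci.descriptor_set(cn)
        nli = ci.nonlinearity_index(ds.lambda1_tp, ds.lambda1_ta,
                                    ds.lambda1, ds.lambda2)
        aggs.append(nli.aggregate)
    # ds/nli now hold the last run; drives are stable across runs
    print(f"\n{name}  (10 runs x 30,000 trials, pc = {cn.pc:.3f})")
    print(f"  lambda1 = {ds.lambda1:+.3f}   lambda2 = {ds.lambda2:+.3f}")
    print(f"  target-present vs absent drive: {ds.lambda1_tp:+.3f} "
          f"vs {ds.lambda1_ta:+.3f}  (marker 1 = {nli.marker1:+.3f})")
    print(f"  nonlinearity aggregate: {np.mean(aggs):+.2f} +- "
          f"{np.std(aggs):.2f}")
    print(f"  h (spatial image): {np.array2string(ds.h, precision=2)}")

print("\nDrives are log-ratios against the decoupled (response-shuffled)")
print("expectation: ~0 means no structure beyond estimation noise.  The")
print("energy model's lambda2 >> 0 exposes its squaring nonlinearity, its")
print("positive marker 1 the missing target-absent image; the template's")
print("aggregate straddles 0 while the energy model's stays positive.")
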