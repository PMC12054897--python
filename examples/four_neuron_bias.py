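"""Decoder bias in the four-neuron wind-direction code.

Four neurons with rectified-cosine tuning (A=1, c=-0.1) and preferred angles
90 degrees apart encode an angle; Gaussian noise (sigma=0.1) corrupts each
response.  We decode 20,000 noisy trials at a stimulus 0.1 rad below a
preferred angle with all three estimators and report the systematic error.
"""

import numpy as np

import popbias as pb

pop = pb.build_population(4)
noise = pb.NoiseSpec("gaussian", sigma=0.1)
theta = 2 * np.pi - 0.1  # 0.1 rad below the preferred angle at 2*pi

r = pb.sample_responses(pop, noise, theta, 20_000, seed=1)
est = pb.decode_trials(r, pop, noise, decoders=("pv", "ml", "bayes"))

print(f"true stimulus: {theta - 2 * np.pi:+.3f} rad (relative to the preferred angle)")
for name, label in [("pv", "population vector"), ("ml", "maximum likelihood"),
                    ("bayes", "Bayesian mean")]:
    dev = pb.wrap_angle(est[name] - theta)
    sem = np.std(dev, ddof=1) / np.sqrt(dev.size)
    print(f"{label:>20}: bias = {np.mean(dev):+.4f} +- {sem:.4f} rad, "
          f"std = {np.std(dev):.4f} rad")
print("A negative bias pushes the estimate away from the preferred angle: even")
print("after averaging thousands of trials the decoders are systematically off,")
print("and the population vector errs several times more than ML/Bayes.")
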