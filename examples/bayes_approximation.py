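"""Analytical approximation of the Bayesian decoder vs Monte Carlo.

The trial-averaged posterior-mean estimate reduces (after dropping the
1/P(r) normalizer) to a single quadrature over candidate stimuli; the
variance to a double quadrature.  Both extend to Poisson spike counts with
Bessel-function and 0F2 kernels.  The approximation runs in milliseconds
where Monte Carlo takes seconds.
"""

import numpy as np

import popbias as pb

pop = pb.build_population(4)
theta = np.pi - 0.1

print("Gaussian noise (sigma=0.1):")
noise = pb.NoiseSpec("gaussian", sigma=0.1)
mc = pb.estimate_bias_variance(pop, noise, theta, "bayes", 20_000, seed=3)
ap = pb.approx_bias(pop, noise, theta)
av = pb.approx_variance(pop, noise, theta)
print(f"  bias:     MC = {mc.bias:+.4f} +- {mc.sem:.4f}   approx = {ap.bias:+.4f}")
print(f"  variance: MC = {mc.variance:.5f}            approx = {av.variance:.5f}")

print("Poisson counts (window T=20):")
noise_p = pb.NoiseSpec("poisson", window=20.0)
mc_p = pb.estimate_bias_variance(pop, noise_p, theta, "bayes", 10_000, seed=4)
ap_p = pb.approx_bias_poisson(pop, 20.0, theta)
av_p = pb.approx_variance_poisson(pop, 20.0, theta, quad_points=301)
print(f"  bias:     MC = {mc_p.bias:+.4f} +- {mc_p.sem:.4f}   approx = {ap_p.bias:+.4f}")
print(f"  variance: MC = {mc_p.variance:.5f}            approx = {av_p.variance:.5f}")
print("The approximation reproduces the sign and shape of the bias while")
print("moderately overestimating its magnitude; variances agree closely.")
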