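"""Decoder variance against the bias-corrected Cramér–Rao bound.

A biased estimator obeys var >= [1+b'(Theta)]^2 / I_F(Theta).  Where the
bias slope b' is negative the corrected bound lies below the naive 1/I_F —
and the Bayesian decoder's measured variance actually gets there.
"""

import numpy as np

import popbias as pb

pop = pb.build_population(4)
noise = pb.NoiseSpec("gaussian", sigma=0.1)
thetas = np.pi + np.arange(-0.24, 0.241, 0.04)

bc = pb.efficiency_curve(pop, noise, "bayes", thetas, n_trials=4000, seed=2)

print(" theta-pi   var      1/I_F   [1+b']^2/I_F  efficiency")
for i in range(len(thetas)):
    flag = "  < 1/I_F" if bc.decoder_variance[i] < bc.bound_uncorrected[i] else ""
    print(f" {thetas[i] - np.pi:+.2f}   {bc.decoder_variance[i]:.5f}  "
          f"{bc.bound_uncorrected[i]:.5f}   {bc.bound_corrected[i]:.5f}     "
          f"{bc.efficiency[i]:.2f}{flag}")
print("Variance always stays above the corrected bound (efficiency <= ~1),")
print("but near the preferred angle it drops below the uncorrected 1/I_F:")
print("ignoring the bias would make the decoder look impossibly good.")
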