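# Methods

## Encoding model

A population of N neurons encodes an angle Θ ∈ [0, 2π).  Preferred angles
are equally spaced: ϕ_k = 2πk/N on the circle (for N = 4 this is the
classic 90°-spaced layout), or ϕ_k = k·d on a line with inter-neuron
distance d.  Two tuning families are supported, both peak-normalized so
that f(ϕ, ϕ) = A:

* rectified cosine  f = A/(1−c) · max(cos(ϕ−Θ) − c, 0), with threshold
  −1 ≤ c < 1.  The active arc where f > 0 spans 2·arccos(c); at the default
  c = −0.1 and N = 4, two neurons are active except within ≈0.1 rad of a
  preferred angle, where a third switches on.  At the rectification kink the
  derivative is defined as 0 (the limit from the inactive side), which keeps
  each neuron's Fisher-information contribution finite.
* von Mises  f = A · exp[(cos(ϕ−Θ) − 1)/w], width w > 0, strictly positive.
  The peak-equals-A normalization makes the two families directly
  comparable.

An optional constant baseline (default 0) can be added to either family; no
specific invariance is claimed for it.

For linear arrays the tuning argument is (Θ−ϕ_k)/d, so the active width in
stimulus units is 2d·arccos(c), and only the central cosine lobe responds
(no periodic replicas).  Everything is then scale-free in units of d, which
is why the linear-array bias is exactly proportional to d.

Noise is either Gaussian additive, r_k = f_k(Θ) + σν with ν ~ N(0,1)
i.i.d., or Poisson: integer counts n_k ~ Poisson(T·f_k(Θ)) over a window T,
consumed by the decoders as counts together with T (this avoids any
rate-versus-count ambiguity in the likelihood).

Defaults throughout: A = 1, c = −0.1, σ = 0.1, N = 4 — a small population in
which roughly two neurons respond to any stimulus.

## Decoders

All decoders receive a single-trial response vector r.

* Population vector: θ̂ = atan2(Σ r_k sin ϕ_k, Σ r_k cos ϕ_k).
* Maximum likelihood: arg-max of the log likelihood over a uniform grid of
  candidate angles covering one period.  The default grid has 10⁴ points
  (resolution 2π/10⁴ ≈ 6·10⁻⁴ rad), so quantization error is well below the
  ~10⁻² rad biases being measured.  Ties break deterministically toward the
  lowest-index candidate; this matters only in noiseless ambiguity
  demonstrations.
* Bayesian least squares: the posterior mean under a flat prior, always in
  the circular resultant-vector form
  θ̂ = atan2(∫ sin θ P(θ|r) dθ, ∫ cos θ P(θ|r) dθ).  For the concentrated
  posteriors that arise here this is numerically identical to the linear
  mean away from the 0/2π seam; using the circular form everywhere keeps one
  code path.

Gaussian log likelihood: −Σ_k (f_k(θ) − r_k)²/(2σ²).  Poisson:
Σ_k [n_k log(T f_k(θ)) − T f_k(θ)] with 0·log 0 := 0; a positive count from
a neuron whose model rate is zero makes the candidate impossible (−∞).
Posteriors are exponentiated after max-subtraction.  The vectorized
trial-decoding path computes the likelihood matrix once per chunk of trials
and shares it between the ML and Bayesian decoders.

## Bias and variance estimation

Bias and variance are computed from wrapped deviations θ̂ − Θ mapped to
(−π, π] — plain statistics on wrapped differences rather than full circular
moments, valid because estimate distributions are narrow and experiment
windows stay away from the 0/2π discontinuity.  The per-angle Monte-Carlo
standard error of the bias is √(var/n).  Default n = 10⁴ trials per angle;
the headline four-neuron bias values use 10⁵ so that ~10⁻³ rad differences
resolve.  Per-angle RNG streams are derived from one root seed via
`numpy.random.SeedSequence`, making whole curves reproducible bit-for-bit.

The min/max-bias summary is taken over the quarter interval [−π/4, 0] to
the left of a preferred angle, with the sign convention that positive means
attraction toward it (for angles right of the preferred angle the sign is
flipped accordingly).  The summary window is anchored at the preferred
angle π rather than 0/2π purely to stay clear of the seam; by symmetry the
choice of preferred angle is immaterial.

Scaling experiments measure max |bias| over a grid spanning one interval
between adjacent preferred angles (symmetry makes one interval sufficient).
Three rules grow the population from N₀ to N:

* none — only density increases;
* amplitude — A scaled by N₀/N, conserving the summed population activity;
* width — for rectified cosine the active arc is scaled by N₀/N (constant
  expected number of simultaneously active neurons, solving
  c′ = cos(arccos(c)·N₀/N)); for von Mises, w is solved numerically
  (brentq, tolerance 1e-8) so the summed tuning mass N·∫f dθ is conserved.
  Note the rectified-cosine rule conserves active count, not integrated
  mass (the two differ by a few percent), which is the intended behaviour.

## Fisher information and the corrected bound

For Gaussian noise I_F(Θ) = (1/σ²) Σ_k f′_k(Θ)², using the analytic tuning
derivatives; inactive rectified-cosine neurons contribute exactly zero.
For the pure cosine (c = −1) this reduces to N A²/(8σ²), θ-independent — a
closed form the tests pin to 1e-10.  Poisson Fisher information is
deliberately not implemented; requesting it raises rather than guessing a
formula.

A biased decoder obeys var(Θ) ≥ [1 + b′(Θ)]²/I_F(Θ).  The bias derivative
b′ is obtained from a bias curve by central finite differences, optionally
after a centered moving average (window 3) to tame Monte-Carlo jitter; an
approximation-backend variant evaluates the analytical bias on the same
grid instead.  Because b′ is itself a Monte-Carlo quantity, bound
comparisons in the tests propagate its standard error
(≈ √2·SEM_bias/(2Δθ), reduced by the smoothing window) into the tolerance
alongside the variance SEM (var·√(2/(n−1))).

Efficiency is the ratio of the corrected bound to the measured variance.

## The Bayesian-decoder approximation

Averaging the posterior-mean estimator over trials involves an
N-dimensional integral over response space.  Dropping the 1/P(r) normalizer
and completing the square reduces it to quadrature over candidate stimuli:

* bias: single quadrature of exp{−Σ_k [f_k(θ)−f_k(Θ)]²/(4σ²)} over one
  period centred on Θ, mean taken in the circular resultant form;
* variance: double quadrature of (θ₁−⟨θ̂⟩)(θ₂−⟨θ̂⟩) against
  Q(θ₁,θ₂) = exp{−(1/6σ²) Σ_k [f_k(θ₁)−f_k(Θ)]² + [f_k(θ₂)−f_k(Θ)]² +
  [f_k(θ₁)−f_k(θ₂)]²}, where ⟨θ̂⟩ is the approximation's own mean estimate
  (not Θ).

The 1/(4σ²) and 1/(6σ²) factors are verified in-suite against brute-force
response-space integrals.  For Poisson counts the response-space sums
evaluate in closed form per neuron:

* bias kernel  e^{−T(f(θ)+f(Θ))} · I₀(2T√(f(θ)f(Θ))), evaluated via the
  exponentially scaled Bessel function `ive` to avoid overflow;
* variance kernel  e^{−T(f(θ₁)+f(θ₂)+f(Θ))} · ₀F₂(;1,1; T³f(θ₁)f(θ₂)f(Θ)),
  with ₀F₂(;1,1;x) = Σ_k x^k/(k!)³ summed directly to relative tolerance
  1e-12 for moderate x and in log space (logsumexp over k·ln x − 3·ln k!)
  for large x.

Both Poisson kernels are uniquely determined by the direct spike-count
summation Σ_n Pois(n;λ₁)Pois(n;λ₂)[Pois(n;λ₃)], which the test suite
verifies to 1e-10.

Quadrature uses uniform grids over one period (the kernels are smooth and
periodic, so the uniform rule is spectrally accurate): 2001 points for the
1-D bias integral, 501 per dimension for the 2-D variance integral — the
2-D default is smaller because the Poisson ₀F₂ kernel is the expensive
part, and the convergence test shows halving the 1-D step changes the bias
by < 1e-6, far below the approximation's own error.  All kernels are
rescaled by their maximum before exponentiation.  Linear arrays integrate
over a local window of ± (half tuning width + 2d) around Θ with a plain
(non-circular) mean; outside that window the kernel is flat at
exp(−Σf_k(Θ)²/4σ²) ≈ 1e-11 at the defaults, negligible.

The approximation moderately overestimates the bias magnitude (it ignores
the normalizer) but reproduces its sign structure, noise dependence and
scaling behaviour; the variance it gives is within a few percent of Monte
Carlo at the defaults.

## What the simulations do and do not show

The generator emulates the idealized study conditions: independent noise,
homogeneous equally spaced populations, a decoder that knows the true
encoding model, and a flat stimulus prior.  Real recordings have correlated
noise, heterogeneous tuning, model mismatch and non-uniform priors — all of
which can add biases of their own; passing tests here say nothing about
those mechanisms, only that the few-active-neurons mechanism is real and
quantitatively as characterized.

Problem sizes in the test suite are chosen to resolve each effect and no
more: 10⁵ trials where ~10⁻³ rad matters, 5·10³–10⁴ for sign/shape checks,
and the analytical backend for scaling sweeps (the same backend choice used
for the linear-array analysis, where Monte Carlo remains available behind a
flag).

## Known limitations and open choices

* The bi-phasic sign structure of the rectified-cosine bias is clearest
  around c ≈ −0.05 at σ = 0.1: at c = −0.1 the attractive lobe is below
  ~3·10⁻⁴ rad and would need millions of trials to resolve, so the
  shape-phenomenology test uses c = −0.05 as its bi-phasic representative.
* Under amplitude scaling our max-bias comes out marginally *below* the
  unscaled case at N ≤ 16 (both backends agree), i.e. the two rules are
  nearly indistinguishable at these sizes; no ordering between them is
  asserted.
* The ML grid decoder has no local refinement (off-by-default quadratic
  refinement was considered and dropped: grid resolution already exceeds
  requirements).
* Poisson efficiency analysis is out of scope (no Poisson Fisher
  information).
* The circular-mean convention is atan2(sine-component, cosine-component)
  throughout.
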