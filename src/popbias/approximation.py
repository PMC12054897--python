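"""Analytical approximation to the Bayesian decoder's bias and variance.

Averaging the posterior-mean estimator over trials involves an intractable
N-dimensional integral over response space; dropping the 1/P(r) normalizer
and completing the square collapses it to low-dimensional quadrature over
candidate stimuli.  For Gaussian noise the trial-averaged estimate becomes

    <θ̂>(Θ) = (1/Z₁) ∫ dθ θ · exp{ −(1/4σ²) Σ_k [f_k(θ) − f_k(Θ)]² }

and the variance is a double quadrature against the kernel

    Q(θ₁,θ₂) = exp{ −(1/6σ²) Σ_k [f_k(θ₁)−f_k(Θ)]² + [f_k(θ₂)−f_k(Θ)]²
                                 + [f_k(θ₁)−f_k(θ₂)]² }

For Poisson spike counts over a window T the response-space sums evaluate in
closed form: the bias kernel is Π_k e^{−T(f_k(θ)+f_k(Θ))} I₀(2T√(f_k(θ)f_k(Θ)))
and the variance kernel is Π_k e^{−T(f_k(θ₁)+f_k(θ₂)+f_k(Θ))}
·₀F₂(;1,1; T³ f_k(θ₁) f_k(θ₂) f_k(Θ)), with ₀F₂(;1,1;x) = Σ_k x^k/(k!)³.
Both Poisson kernels are fixed by the direct spike-count summation
Σ_n Pois(n;λ₁)Pois(n;λ₂)[Pois(n;λ₃)], which the test suite verifies.

The approximation moderately overestimates the bias magnitude but reproduces
its full parameter dependence (sign structure, noise dependence, scaling).
All means are taken in the circular resultant-vector form on the circle, and
as plain means on the line (linear arrays).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ive, logsumexp

from .encoding import ConfigurationError, NoiseSpec, Population, population_rates
from .experiments import wrap_angle

__all__ = [
    "ApproxResult",
    "approx_bias",
    "approx_variance",
    "approx_bias_gaussian",
    "approx_variance_gaussian",
    "approx_bias_poisson",
    "approx_variance_poisson",
    "hyp0f2",
    "log_hyp0f2",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ApproxResult:
    """Result of the bias/variance approximation at one true stimulus angle."""

    theta_true: float
    mean_estimate: float
    bias: float
    variance: float | None
    z1: float
    z2: float | None
    resolution: float

    def __post_init__(self):
        if not self.z1 > 0:
            raise ValueError("normalizer Z1 must be positive")
        if self.z2 is not None and not self.z2 > 0:
            raise ValueError("normalizer Z2 must be positive")


def _quad_grid(pop: Population, theta: float, n: int) -> tuple[np.ndarray, float]:
    """Quadrature nodes around the true stimulus and the node spacing.

    Circular populations integrate over one full period [Θ−π, Θ+π) with the
    uniform (trapezoidal-equivalent) rule; linear arrays integrate over a
    local window wide enough to contain all kernel mass.
    """
    if pop.geometry == "circular":
        h = TWO_PI / n
        return theta + np.linspace(-np.pi, np.pi, n, endpoint=False), h
    d = pop.spacing
    half_width = d * np.arccos(pop.tuning.threshold) if pop.tuning.family == "rectified_cosine" else np.pi * d
    L = half_width + 2.0 * d
    grid = theta + np.linspace(-L, L, n)
    return grid, grid[1] - grid[0]


def _mean_of_kernel(pop, grid, log_k, theta):
    """Normalized kernel, its mass, and the kernel-weighted mean estimate."""
    k = np.exp(log_k - np.max(log_k))  # mandated rescale by the kernel max
    mass = float(np.sum(k))
    if mass == 0.0:
        raise FloatingPointError("kernel mass underflow")
    if pop.geometry == "circular":
        m = float(np.arctan2(np.dot(k, np.sin(grid)), np.dot(k, np.cos(grid))))
        m = float(np.mod(m, TWO_PI))
    else:
        m = float(np.dot(k, grid) / mass)
    return k, mass, m


def _log_bias_kernel(pop: Population, noise: NoiseSpec, grid: np.ndarray, theta: float) -> np.ndarray:
    F = population_rates(pop, grid)  # (M, N)
    f0 = population_rates(pop, float(theta))
    if noise.kind == "gaussian":
        return -np.sum((F - f0) ** 2, axis=1) / (4.0 * noise.sigma**2)
    T = noise.window
    lam, lam0 = T * F, T * f0
    x = 2.0 * np.sqrt(lam * lam0)
    # log I0(x) = x + log ive(0, x), stable for large arguments
    return np.sum(-(lam + lam0) + x + np.log(ive(0, x)), axis=1)


def approx_bias(pop: Population, noise: NoiseSpec, theta: float, quad_points: int = 2001) -> ApproxResult:
    """Approximate trial-averaged Bayesian estimate and bias at ``theta``."""
    _check_noise(noise)
    grid, h = _quad_grid(pop, theta, quad_points)
    log_k = _log_bias_kernel(pop, noise, grid, theta)
    _, mass, m = _mean_of_kernel(pop, grid, log_k, theta)
    bias = wrap_angle(m - theta) if pop.geometry == "circular" else m - theta
    return ApproxResult(float(theta), m, float(bias), None, mass * h, None, h)


def approx_variance(pop: Population, noise: NoiseSpec, theta: float, quad_points: int = 501) -> ApproxResult:
    """Approximate variance (and bias) of the Bayesian estimator at ``theta``.

    The mean subtracted inside the double quadrature is the approximation's
    own mean estimate, recomputed on the same nodes.
    """
    _check_noise(noise)
    grid, h = _quad_grid(pop, theta, quad_points)
    log_k1 = _log_bias_kernel(pop, noise, grid, theta)
    _, z1_mass, m = _mean_of_kernel(pop, grid, log_k1, theta)
    F = population_rates(pop, grid)  # (M, N)
    f0 = population_rates(pop, float(theta))
    if noise.kind == "gaussian":
        a = np.sum((F - f0) ** 2, axis=1)
        s = np.sum(F * F, axis=1)
        cross = s[:, None] + s[None, :] - 2.0 * (F @ F.T)
        log_q = -(a[:, None] + a[None, :] + cross) / (6.0 * noise.sigma**2)
    else:
        T = noise.window
        log_q = np.zeros((len(grid), len(grid)))
        for k in range(pop.n_neurons):
            fi = F[:, k]
            x = (T**3) * np.multiply.outer(fi, fi) * f0[k]
            log_q += log_hyp0f2(x) - T * (fi[:, None] + fi[None, :] + f0[k])
    q = np.exp(log_q - np.max(log_q))
    z2_mass = float(np.sum(q))
    if pop.geometry == "circular":
        dev = wrap_angle(grid - m)
    else:
        dev = grid - m
    variance = float(dev @ q @ dev / z2_mass)
    bias = wrap_angle(m - theta) if pop.geometry == "circular" else m - theta
    return ApproxResult(float(theta), m, float(bias), variance, z1_mass * h, z2_mass * h * h, h)


def _check_noise(noise: NoiseSpec) -> None:
    if noise.kind == "gaussian" and noise.sigma <= 0:
        raise ConfigurationError("the approximation requires sigma > 0")


# -- spec'd convenience signatures ------------------------------------------

def approx_bias_gaussian(pop: Population, sigma: float, theta: float, quad_points: int = 2001) -> ApproxResult:
    return approx_bias(pop, NoiseSpec("gaussian", sigma=sigma), theta, quad_points)


def approx_variance_gaussian(pop: Population, sigma: float, theta: float, quad_points: int = 501) -> ApproxResult:
    return approx_variance(pop, NoiseSpec("gaussian", sigma=sigma), theta, quad_points)


def approx_bias_poisson(pop: Population, window: float, theta: float, quad_points: int = 2001) -> ApproxResult:
    return approx_bias(pop, NoiseSpec("poisson", window=window), theta, quad_points)


def approx_variance_poisson(pop: Population, window: float, theta: float, quad_points: int = 501) -> ApproxResult:
    return approx_variance(pop, NoiseSpec("poisson", window=window), theta, quad_points)


# -- generalized hypergeometric 0F2(;1,1;x) ---------------------------------

_MAX_TERMS = 100_000


def hyp0f2(x):
    """₀F₂(;1,1;x) = Σ_k x^k / (k!)³, summed to relative tolerance 1e-12.

    Scalar or array input; large nonnegative arguments are evaluated in log
    space to avoid overflow.
    """
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    out = np.empty_like(x_arr)
    # log 0F2(x) ~ 3 x^(1/3) for large x; keep direct summation clear of overflow
    big = x_arr > 200.0**3
    if np.any(~big):
        out[~big] = _hyp0f2_direct(x_arr[~big])
    if np.any(big):
        out[big] = np.exp(log_hyp0f2(x_arr[big]))
    return float(out[0]) if scalar else out


def _hyp0f2_direct(x: np.ndarray) -> np.ndarray:
    total = np.ones_like(x)
    term = np.ones_like(x)
    for k in range(_MAX_TERMS):
        term = term * x / (k + 1.0) ** 3
        total = total + term
        if np.all(np.abs(term) <= 1e-12 * np.abs(total)):
            return total
    raise ArithmeticError("0F2 series did not converge")  # unreachable for finite x


def log_hyp0f2(x):
    """log ₀F₂(;1,1;x) for x ≥ 0, via log-space summation of the series."""
    scalar = np.ndim(x) == 0
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr < 0):
        raise ValueError("log_hyp0f2 requires x >= 0")
    shape = x_arr.shape
    flat = x_arr.reshape(-1)
    xmax = float(np.max(flat)) if flat.size else 0.0
    k_peak = xmax ** (1.0 / 3.0)
    n_terms = int(k_peak + 12.0 * np.sqrt(k_peak + 1.0) + 20.0)
    ks = np.arange(n_terms)
    log_fact3 = 3.0 * gammaln(ks + 1.0)
    out = np.empty(flat.size)
    # x == 0 contributes only the k=0 term; a large-negative stand-in for
    # log(0) avoids 0*(-inf) NaNs in the outer product below
    log_x = np.where(flat > 0, np.log(np.where(flat > 0, flat, 1.0)), -760.0)
    block = max(1, 2**22 // max(n_terms, 1))
    for lo in range(0, flat.size, block):
        hi = min(lo + block, flat.size)
        terms = np.multiply.outer(ks, log_x[lo:hi]) - log_fact3[:, None]
        out[lo:hi] = logsumexp(terms, axis=0)
    out = out.reshape(shape)
    return float(out[0]) if scalar else out
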