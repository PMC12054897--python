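"""Fisher information, bias-corrected Cramér–Rao bound, decoder efficiency.

For Gaussian noise the Fisher information of the population is
``I_F(Θ) = (1/σ²) Σ_k [f'_k(Θ)]²``.  An unbiased estimator obeys
``var ≥ 1/I_F``; a decoder with bias b(Θ) instead obeys

    var(Θ) ≥ [1 + b'(Θ)]² / I_F(Θ)

so where the bias has negative slope the achievable variance drops *below*
the naive 1/I_F.  Efficiency is the ratio of the corrected bound to the
actual decoder variance (1 when the decoder saturates the bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoding import NoiseSpec, Population, population_derivatives
from .experiments import BiasCurve, bias_curve

__all__ = [
    "BoundCurve",
    "InfiniteInformationError",
    "fisher_information",
    "corrected_cr_bound",
    "bias_derivative",
    "curve_derivative",
    "efficiency_curve",
]


class InfiniteInformationError(ValueError):
    """sigma = 0 implies infinite Fisher information."""


@dataclass(frozen=True)
class BoundCurve:
    """Per-angle information bounds next to a decoder's measured variance."""

    thetas: np.ndarray
    fisher_info: np.ndarray
    bound_uncorrected: np.ndarray   # 1 / I_F
    bias_deriv: np.ndarray          # b'(theta)
    bound_corrected: np.ndarray     # (1 + b')^2 / I_F
    decoder_variance: np.ndarray
    efficiency: np.ndarray          # corrected bound / variance
    variance_sem: np.ndarray        # MC standard error of the variance
    n_trials: int
    decoder: str


def fisher_information(pop: Population, sigma: float, theta):
    """Gaussian-noise Fisher information ``(1/σ²) Σ_k f'_k(θ)²``.

    Inactive rectified-cosine neurons have zero slope and contribute exactly
    nothing.  Poisson Fisher information is deliberately not provided.
    """
    if sigma == 0:
        raise InfiniteInformationError("sigma = 0: Fisher information diverges")
    if sigma < 0:
        raise ValueError("sigma must be positive")
    d = population_derivatives(pop, theta)
    return np.sum(d * d, axis=-1) / sigma**2


def corrected_cr_bound(fisher, bias_deriv):
    """Bias-corrected Cramér–Rao bound ``[1 + b']² / I_F``."""
    fisher = np.asarray(fisher, dtype=float)
    if np.any(fisher <= 0):
        raise ValueError("Fisher information must be positive")
    return (1.0 + np.asarray(bias_deriv, dtype=float)) ** 2 / fisher


def curve_derivative(curve: BiasCurve, smooth_window: int = 0) -> np.ndarray:
    """b'(θ) on the curve's own grid by central finite differences.

    ``smooth_window`` > 1 first applies a centered moving average to the bias
    (edge-shrunk), taming Monte-Carlo jitter before differentiation.
    """
    b = curve.bias
    if smooth_window and smooth_window > 1:
        k = smooth_window
        pad = k // 2
        padded = np.concatenate([b[:1].repeat(pad), b, b[-1:].repeat(pad)])
        b = np.convolve(padded, np.ones(k) / k, mode="valid")
    return np.gradient(b, curve.thetas)


def bias_derivative(curve: BiasCurve, theta: float, smooth_window: int = 0) -> float:
    """b'(Θ) at one angle, interpolated from the curve's finite differences."""
    th = curve.thetas
    if theta < th[0] - 1e-12 or theta > th[-1] + 1e-12:
        raise ValueError("theta outside the bias curve's support")
    if np.isclose(theta, th[0]) or np.isclose(theta, th[-1]):
        warnings.warn("theta at curve boundary: one-sided difference", stacklevel=2)
    deriv = curve_derivative(curve, smooth_window)
    return float(np.interp(theta, th, deriv))


def efficiency_curve(
    pop: Population,
    noise: NoiseSpec,
    decoder: str = "bayes",
    theta_grid=None,
    n_trials: int = 10_000,
    seed=0,
    smooth_window: int = 3,
    grid=None,
    backend: str = "mc",
) -> BoundCurve:
    """Assemble Fisher information, bounds and measured variance per angle.

    The bias derivative comes from the Monte-Carlo bias curve (or, with
    ``backend="approx"``, from the analytical approximation evaluated on the
    same grid) by central differences with optional moving-average smoothing.
    """
    if noise.kind != "gaussian":
        raise NotImplementedError("efficiency analysis is defined for Gaussian noise")
    thetas = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    curve = bias_curve(pop, noise, thetas, decoder, n_trials, seed, grid)
    if backend == "approx":
        from .approximation import approx_bias

        ab = np.array([approx_bias(pop, noise, t).bias for t in thetas])
        dcurve = BiasCurve(thetas, ab, curve.variance, n_trials, curve.bias_sem, decoder)
        bprime = curve_derivative(dcurve, smooth_window=0)
    else:
        bprime = curve_derivative(curve, smooth_window)
    fisher = fisher_information(pop, noise.sigma, thetas)
    corrected = corrected_cr_bound(fisher, bprime)
    variance = curve.variance
    var_sem = variance * np.sqrt(2.0 / (n_trials - 1))
    return BoundCurve(
        thetas,
        fisher,
        1.0 / fisher,
        bprime,
        corrected,
        variance,
        corrected / variance,
        var_sem,
        n_trials,
        decoder,
    )
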