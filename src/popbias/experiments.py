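"""Monte-Carlo estimation of decoder bias and variance across stimulus angles.

The bias of a decoder is ``b(Θ) = <θ̂> − Θ``, the trial average of the
estimate minus the true stimulus.  Deviations are computed as wrapped
differences in (−π, π], which coincides with ordinary statistics as long as
stimuli are kept away from the circular discontinuity at 0/2π (which all the
default experiment windows are).

Besides per-angle estimation this module provides the summary used throughout
the analyses — the minimum and maximum bias over the quarter-interval to the
left of a preferred angle, with the sign convention that positive means
attraction toward the preferred stimulus — plus population-size scaling
experiments and the linear-array variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .encoding import (
    ConfigurationError,
    NoiseSpec,
    Population,
    TuningModel,
    build_population,
    population_rates,
    sample_responses,
    scale_population,
)
from .decoders import DecodeGrid, decode_trials

__all__ = [
    "BiasStats",
    "BiasCurve",
    "BiasSummary",
    "ExperimentError",
    "IllDefinedBiasError",
    "wrap_angle",
    "estimate_bias_variance",
    "bias_curve",
    "min_max_bias",
    "noise_sweep",
    "scaling_experiment",
    "linear_array_bias",
]

TWO_PI = 2.0 * np.pi


class ExperimentError(RuntimeError):
    pass


class IllDefinedBiasError(ExperimentError):
    """Some stimuli activate no neuron at all, so the bias is undefined."""


def wrap_angle(x):
    """Map angle difference(s) to the interval (−π, π]."""
    d = np.mod(np.asarray(x, dtype=float) + np.pi, TWO_PI) - np.pi
    return np.where(d == -np.pi, np.pi, d) if np.ndim(d) else (np.pi if d == -np.pi else float(d))


class BiasStats(NamedTuple):
    bias: float
    variance: float
    sem: float


@dataclass(frozen=True)
class BiasCurve:
    """Per-angle Monte-Carlo bias and variance for one decoder."""

    thetas: np.ndarray
    bias: np.ndarray
    variance: np.ndarray
    n_trials: int
    bias_sem: np.ndarray
    decoder: str
    fingerprint: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.thetas,
                "bias": self.bias,
                "variance": self.variance,
                "bias_sem": self.bias_sem,
            }
        )


@dataclass(frozen=True)
class BiasSummary:
    min_bias: float
    max_bias: float
    window: tuple = (-np.pi / 4, 0.0)

    def __post_init__(self):
        if self.min_bias > self.max_bias:
            raise ValueError("min_bias must not exceed max_bias")


def _fingerprint(pop: Population, noise: NoiseSpec, decoder: str, n_trials: int, seed) -> str:
    t = pop.tuning
    return (
        f"family={t.family} A={t.amplitude} c={t.threshold} w={t.width} "
        f"N={pop.n_neurons} geometry={pop.geometry} noise={noise.kind} "
        f"sigma={noise.sigma} T={noise.window} decoder={decoder} "
        f"n_trials={n_trials} seed={seed}"
    )


def estimate_bias_variance(
    pop: Population,
    noise: NoiseSpec,
    theta: float,
    decoder: str = "bayes",
    n_trials: int = 10_000,
    seed=0,
    grid: DecodeGrid | None = None,
) -> BiasStats:
    """Monte-Carlo bias, variance and bias SEM of one decoder at one angle.

    Poisson responses are decoded as counts with the window carried by the
    noise spec.  Deterministic for a given seed.
    """
    if n_trials < 100:
        raise ExperimentError(f"n_trials must be >= 100, got {n_trials}")
    r = sample_responses(pop, noise, theta, n_trials, seed)
    est = decode_trials(r, pop, noise, decoders=(decoder,), grid=grid)[decoder]
    dev = wrap_angle(est - theta)
    bias = float(np.mean(dev))
    variance = float(np.var(dev, ddof=1))
    return BiasStats(bias, variance, float(np.sqrt(variance / n_trials)))


def _theta_seeds(seed, n: int) -> np.ndarray:
    # deterministic per-angle streams derived from one root seed
    return np.random.SeedSequence(seed).generate_state(n)


def bias_curve(
    pop: Population,
    noise: NoiseSpec,
    theta_grid,
    decoder: str = "bayes",
    n_trials: int = 10_000,
    seed=0,
    grid: DecodeGrid | None = None,
) -> BiasCurve:
    """Bias/variance across a grid of stimulus angles (per-angle seeds derived
    from one root seed, so whole curves are reproducible)."""
    thetas = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    seeds = _theta_seeds(seed, len(thetas))
    bias = np.empty_like(thetas)
    var = np.empty_like(thetas)
    for i, (th, s) in enumerate(zip(thetas, seeds)):
        st = estimate_bias_variance(pop, noise, th, decoder, n_trials, int(s), grid)
        bias[i], var[i] = st.bias, st.variance
    return BiasCurve(
        thetas,
        bias,
        var,
        n_trials,
        np.sqrt(var / n_trials),
        decoder,
        _fingerprint(pop, noise, decoder, n_trials, seed),
    )


def min_max_bias(
    curve: BiasCurve,
    window=(-np.pi / 4, 0.0),
    preferred: float = np.pi,
) -> BiasSummary:
    """Min/max bias over ``window`` relative to a preferred angle.

    Sign convention: positive bias means attraction toward the preferred
    stimulus.  For the default window (left of the preferred angle) this is
    the raw bias; for angles to the right the sign is flipped.
    """
    rel = wrap_angle(curve.thetas - preferred)
    lo, hi = window
    mask = (rel >= lo - 1e-12) & (rel <= hi + 1e-12)
    if not np.any(mask):
        raise ExperimentError("bias curve does not cover the requested window")
    signed = np.where(rel[mask] > 1e-12, -curve.bias[mask], curve.bias[mask])
    return BiasSummary(float(np.min(signed)), float(np.max(signed)), tuple(window))


def _interval_thetas(pop: Population, n_theta: int) -> np.ndarray:
    """Interior grid spanning one interval between adjacent preferred angles,
    chosen near π (far from the 0/2π discontinuity)."""
    phis = pop.preferred_angles
    k_hi = min(max(int(np.searchsorted(phis, np.pi)), 1), pop.n_neurons - 1)
    lo, hi = phis[k_hi - 1], phis[k_hi]
    return np.linspace(lo, hi, n_theta + 2)[1:-1]


def _window_thetas(preferred: float, window, n_theta: int) -> np.ndarray:
    lo, hi = window
    return preferred + np.linspace(lo, hi, n_theta)


def _bias_over(
    pop: Population,
    noise: NoiseSpec,
    thetas: np.ndarray,
    decoder: str,
    backend: str,
    n_trials: int,
    seed,
    grid: DecodeGrid | None,
    quad_points: int,
) -> np.ndarray:
    if backend == "mc":
        return bias_curve(pop, noise, thetas, decoder, n_trials, seed, grid).bias
    if backend == "approx":
        if decoder != "bayes":
            raise ExperimentError("the analytical approximation backend covers the Bayesian decoder only")
        from .approximation import approx_bias

        return np.array([approx_bias(pop, noise, th, quad_points=quad_points).bias for th in thetas])
    raise ExperimentError(f"backend must be 'mc' or 'approx', got {backend!r}")


def noise_sweep(
    pop: Population,
    sigmas,
    decoder: str = "bayes",
    backend: str = "mc",
    window=(-np.pi / 4, 0.0),
    preferred: float = np.pi,
    n_theta: int = 21,
    n_trials: int = 10_000,
    seed=0,
    grid: DecodeGrid | None = None,
    quad_points: int = 2001,
) -> pd.DataFrame:
    """Min/max attraction-signed bias versus Gaussian noise level."""
    thetas = _window_thetas(preferred, window, n_theta)
    rows = []
    for s in sigmas:
        noise = NoiseSpec("gaussian", sigma=float(s))
        bias = _bias_over(pop, noise, thetas, decoder, backend, n_trials, seed, grid, quad_points)
        curve = BiasCurve(thetas, bias, np.zeros_like(bias), max(n_trials, 100),
                          np.zeros_like(bias), decoder)
        summ = min_max_bias(curve, window, preferred)
        rows.append({"sigma": float(s), "min_bias": summ.min_bias, "max_bias": summ.max_bias})
    return pd.DataFrame(rows)


def scaling_experiment(
    base_pop: Population,
    noise: NoiseSpec,
    decoder: str = "bayes",
    n_list=(4, 8, 16),
    mode: str = "none",
    n_trials: int = 10_000,
    seed=0,
    backend: str = "mc",
    n_theta: int = 9,
    grid: DecodeGrid | None = None,
    quad_points: int = 2001,
) -> pd.DataFrame:
    """Maximum absolute bias versus population size under a scaling rule.

    The maximum is taken over a grid of stimuli spanning one interval between
    two adjacent preferred angles (symmetry makes one interval sufficient).
    """
    n_list = list(n_list)
    if any(b > a for b, a in zip(n_list, n_list[1:])):
        raise ExperimentError("n_list must be ascending")
    rows = []
    for n_new in n_list:
        pop = scale_population(base_pop, n_new, mode)
        thetas = _interval_thetas(pop, n_theta)
        bias = _bias_over(pop, noise, thetas, decoder, backend, n_trials, seed, grid, quad_points)
        rows.append({"N": n_new, "max_abs_bias": float(np.max(np.abs(bias)))})
    return pd.DataFrame(rows)


def linear_array_bias(
    tuning: TuningModel,
    spacing_list,
    noise: NoiseSpec,
    decoder: str = "bayes",
    backend: str = "approx",
    n_theta: int = 9,
    n_trials: int = 10_000,
    seed=0,
    quad_points: int = 2001,
) -> pd.DataFrame:
    """Min/max bias in a long 1-D array versus inter-neuron distance d.

    The tuning argument is measured in units of d, so the rectified-cosine
    active width in stimulus space is ``2 d arccos(c)``.  A width below 1 (in
    units of d) leaves some stimuli with no active neuron, which makes the
    bias ill-defined and raises.  Stimuli span the half interval to the left
    of a central neuron, far from the array ends; by construction the bias is
    proportional to d.  Default backend is the analytical approximation.
    """
    if tuning.family != "rectified_cosine":
        raise ConfigurationError("linear_array_bias is defined for rectified-cosine tuning")
    width_units_d = 2.0 * np.arccos(tuning.threshold)
    if width_units_d < 1.0:
        raise IllDefinedBiasError(
            f"tuning width {width_units_d:.3f}·d < 1·d: some stimuli activate no neuron"
        )
    from .approximation import approx_bias

    rows = []
    for d in spacing_list:
        d = float(d)
        half_width = d * np.arccos(tuning.threshold)
        # enough neurons that the central interval is far from the ends
        reach = 2.0 * half_width + 4.0 * d
        n_side = int(np.ceil(reach / d)) + 1
        n_neurons = 2 * n_side + 1
        pop = build_population(n_neurons, "linear", tuning, spacing=d)
        center = pop.preferred_angles[n_side]  # middle neuron
        thetas = center + np.linspace(-d / 2, 0.0, n_theta + 1)[:-1]
        if backend == "approx":
            if decoder != "bayes":
                raise ExperimentError("approximation backend covers the Bayesian decoder only")
            bias = np.array(
                [approx_bias(pop, noise, th, quad_points=quad_points).bias for th in thetas]
            )
        elif backend == "mc":
            bias = _linear_mc_bias(pop, noise, thetas, decoder, n_trials, seed)
        else:
            raise ExperimentError(f"backend must be 'mc' or 'approx', got {backend!r}")
        rows.append(
            {"d": d, "min_bias": float(np.min(bias)), "max_bias": float(np.max(bias))}
        )
    return pd.DataFrame(rows)


def _linear_mc_bias(pop, noise, thetas, decoder, n_trials, seed):
    """Monte-Carlo bias on the line: grid posterior over a local window with a
    plain (non-circular) mean / arg-max."""
    if noise.kind != "gaussian":
        raise ExperimentError("linear-array Monte Carlo supports Gaussian noise")
    d = pop.spacing
    half_width = d * np.arccos(pop.tuning.threshold)
    seeds = _theta_seeds(seed, len(thetas))
    out = np.empty(len(thetas))
    for i, (th, s) in enumerate(zip(thetas, seeds)):
        cand = th + np.linspace(-(half_width + 2 * d), half_width + 2 * d, 4001)
        F = population_rates(pop, cand)
        r = sample_responses(pop, noise, th, n_trials, int(s))
        s2 = noise.sigma**2
        L = (r @ F.T - 0.5 * np.sum(F * F, axis=1)) / s2
        if decoder == "ml":
            est = cand[np.argmax(L, axis=1)]
        elif decoder == "bayes":
            W = np.exp(L - np.max(L, axis=1, keepdims=True))
            est = (W @ cand) / np.sum(W, axis=1)
        else:
            raise ExperimentError("linear-array Monte Carlo supports 'ml' or 'bayes'")
        out[i] = np.mean(est - th)
    return out
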