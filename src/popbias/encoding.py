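"""Encoding model: tuning curves, population geometry, and noisy responses.

The model is a small population of orientation/direction-selective neurons
(the canonical example being the four-neuron cricket cercal wind-direction
system).  Each neuron k has a preferred angle ``phi_k`` and a tuning curve
``f_k(theta)`` drawn from one of two families:

* rectified cosine:  ``f = A/(1-c) * max(cos(phi - theta) - c, 0)`` — the
  threshold ``c`` (−1 ≤ c < 1) sets the tuning width; the active arc where
  f > 0 has width ``2*arccos(c)``.
* von Mises:  ``f = A * exp[(cos(phi - theta) - 1)/w]`` — smooth, strictly
  positive, peak-normalized so that ``f(phi, phi) = A``.

Responses are either Gaussian (``r_k = f_k + sigma*nu``) or Poisson spike
counts over a window T (``n_k ~ Poisson(T f_k)``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e

__all__ = [
    "TuningModel",
    "Population",
    "NoiseSpec",
    "ConfigurationError",
    "tuning_rate",
    "tuning_derivative",
    "build_population",
    "scale_population",
    "population_rates",
    "population_derivatives",
    "sample_responses",
]

TWO_PI = 2.0 * np.pi


class ConfigurationError(ValueError):
    """Invalid model or population configuration."""


@dataclass(frozen=True)
class TuningModel:
    """Parametric tuning-curve family shared by all neurons of a population.

    Parameters
    ----------
    family:
        ``"rectified_cosine"`` or ``"von_mises"``.
    amplitude:
        Peak response A (rate units; dimensionless by default).
    threshold:
        Rectification threshold c, −1 ≤ c < 1 (rectified cosine only).
    width:
        Width parameter w > 0 (von Mises only).
    baseline:
        Optional constant background added to the tuning curve (default 0).
    """

    family: Literal["rectified_cosine", "von_mises"]
    amplitude: float = 1.0
    threshold: float | None = None
    width: float | None = None
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("rectified_cosine", "von_mises"):
            raise ConfigurationError(
                f"family must be 'rectified_cosine' or 'von_mises', got {self.family!r}"
            )
        if self.amplitude <= 0:
            raise ConfigurationError(f"amplitude must be > 0, got {self.amplitude}")
        if self.baseline < 0:
            raise ConfigurationError(f"baseline must be >= 0, got {self.baseline}")
        if self.family == "rectified_cosine":
            c = self.threshold
            if c is None or not (-1.0 <= c < 1.0):
                raise ConfigurationError(
                    f"threshold c must satisfy -1 <= c < 1, got {c}"
                )
        else:
            w = self.width
            if w is None or w <= 0:
                raise ConfigurationError(f"width w must be > 0, got {w}")


@dataclass(frozen=True)
class Population:
    """Ordered set of neurons with preferred angles and a shared tuning model.

    ``geometry="circular"`` places N preferred angles equally spaced on the
    circle, ``phi_k = 2*pi*k/N`` for k = 1..N (for N = 4 this is the classic
    pi/2, pi, 3*pi/2, 2*pi layout).  ``geometry="linear"`` models a long 1-D
    array with inter-neuron spacing d; there the tuning argument is measured
    in units of d, so the active arc of a rectified cosine spans
    ``2*d*arccos(c)`` of stimulus space, and the single central lobe of the
    cosine is used (no periodic replicas).
    """

    n_neurons: int
    preferred_angles: np.ndarray
    geometry: Literal["circular", "linear"]
    tuning: TuningModel
    spacing: float | None = None

    def __post_init__(self) -> None:
        phis = np.asarray(self.preferred_angles, dtype=float)
        object.__setattr__(self, "preferred_angles", phis)
        if self.n_neurons < 1 or phis.shape != (self.n_neurons,):
            raise ConfigurationError("preferred_angles must have length n_neurons >= 1")
        if self.n_neurons > 1 and not np.all(np.diff(phis) > 0):
            raise ConfigurationError("preferred_angles must be strictly increasing")
        if self.geometry == "linear" and (self.spacing is None or self.spacing <= 0):
            raise ConfigurationError("linear geometry requires spacing > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Observation noise: Gaussian additive (sigma) or Poisson counts (window T)."""

    kind: Literal["gaussian", "poisson"]
    sigma: float | None = None
    window: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "gaussian":
            if self.sigma is None or self.sigma < 0:
                raise ConfigurationError(f"gaussian noise requires sigma >= 0, got {self.sigma}")
        elif self.kind == "poisson":
            if self.window is None or self.window <= 0:
                raise ConfigurationError(f"poisson noise requires window T > 0, got {self.window}")
        else:
            raise ConfigurationError(f"noise kind must be 'gaussian' or 'poisson', got {self.kind!r}")


def _delta(phi, theta):
    return np.subtract.outer(np.asarray(theta, dtype=float), np.asarray(phi, dtype=float))


def tuning_rate(model: TuningModel, phi, theta):
    """Mean response of a neuron with preferred angle ``phi`` to stimulus ``theta``.

    Both arguments broadcast; the result is 2*pi-periodic in theta and
    symmetric about phi.
    """
    d = np.cos(np.asarray(theta, dtype=float) - np.asarray(phi, dtype=float))
    if model.family == "rectified_cosine":
        c = model.threshold
        f = model.amplitude / (1.0 - c) * np.maximum(d - c, 0.0)
    else:
        f = model.amplitude * np.exp((d - 1.0) / model.width)
    return f + model.baseline


def tuning_derivative(model: TuningModel, phi, theta):
    """Analytic derivative of ``tuning_rate`` with respect to theta.

    At the rectification kink of the cosine family the derivative is defined
    as 0 (the limit from the inactive side), which keeps the Fisher
    information contribution of a neuron that is just switching on finite.
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    cosd = np.cos(theta - phi)
    # d/dtheta cos(theta - phi) = -sin(theta - phi) = sin(phi - theta)
    sind = np.sin(phi - theta)
    if model.family == "rectified_cosine":
        c = model.threshold
        return np.where(cosd > c, model.amplitude / (1.0 - c) * sind, 0.0)
    w = model.width
    return model.amplitude * np.exp((cosd - 1.0) / w) * sind / w


def build_population(
    n_neurons: int,
    geometry: str = "circular",
    tuning: TuningModel | None = None,
    spacing: float | None = None,
) -> Population:
    """Construct an equally spaced population.

    Circular: ``phi_k = 2*pi*k/N`` for k = 1..N.  Linear: ``phi_k = k*d``.
    """
    if n_neurons < 1:
        raise ConfigurationError(f"n_neurons must be >= 1, got {n_neurons}")
    if tuning is None:
        tuning = TuningModel("rectified_cosine", amplitude=1.0, threshold=-0.1)
    if geometry == "circular":
        phis = TWO_PI * np.arange(1, n_neurons + 1) / n_neurons
        return Population(n_neurons, phis, "circular", tuning)
    if geometry == "linear":
        if spacing is None:
            raise ConfigurationError("linear geometry requires spacing")
        phis = spacing * np.arange(1, n_neurons + 1, dtype=float)
        return Population(n_neurons, phis, "linear", tuning, spacing)
    raise ConfigurationError(f"geometry must be 'circular' or 'linear', got {geometry!r}")


def _von_mises_mass(w: float) -> float:
    # integral over one period of exp[(cos x - 1)/w] = 2*pi*exp(-1/w)*I0(1/w),
    # evaluated with the scaled Bessel function so tiny widths do not overflow
    return TWO_PI * i0e(1.0 / w)


def scale_population(base: Population, n_new: int, mode: str = "none") -> Population:
    """Grow a circular population from base.N to ``n_new`` neurons.

    mode="none"
        Only the density of preferred angles increases; tuning is unchanged.
    mode="amplitude"
        Amplitude rescaled by base.N/n_new so the summed population activity
        (mean activity) is conserved.
    mode="width"
        Tuning narrowed so sparsity is preserved.  Rectified cosine: the
        active arc 2*arccos(c) is scaled by base.N/n_new (constant expected
        number of simultaneously active neurons).  Von Mises: w is solved
        numerically (tolerance 1e-8) so the summed tuning mass
        ``N * ∫ f dθ`` over one period is conserved.
    """
    if base.geometry != "circular":
        raise ConfigurationError("scale_population applies to circular populations")
    if n_new < base.n_neurons:
        raise ConfigurationError(f"n_new must be >= base population size, got {n_new}")
    ratio = base.n_neurons / n_new
    t = base.tuning
    if n_new == base.n_neurons:
        return base
    if mode == "none":
        new_t = t
    elif mode == "amplitude":
        new_t = replace(t, amplitude=t.amplitude * ratio)
    elif mode == "width":
        if t.family == "rectified_cosine":
            arc = np.arccos(t.threshold) * ratio
            c_new = float(np.cos(arc))
            if c_new >= 1.0:
                raise ConfigurationError("width scaling infeasible: required c >= 1")
            new_t = replace(t, threshold=c_new)
        else:
            target = base.n_neurons * _von_mises_mass(t.width) / n_new

            def gap(w):
                return _von_mises_mass(w) - target

            w_new = brentq(gap, 1e-9, t.width, xtol=1e-8, rtol=1e-12)
            new_t = replace(t, width=float(w_new))
    else:
        raise ConfigurationError(f"mode must be 'none', 'amplitude' or 'width', got {mode!r}")
    return build_population(n_new, "circular", new_t)


def population_rates(pop: Population, theta) -> np.ndarray:
    """Noiseless tuning vector(s) f_k(theta); shape ``theta.shape + (N,)``.

    For linear geometry the tuning argument is (theta - phi_k)/d and only the
    central cosine lobe (|argument| <= pi) responds.
    """
    theta = np.asarray(theta, dtype=float)
    if pop.geometry == "circular":
        d = theta[..., None] - pop.preferred_angles
        return tuning_rate(pop.tuning, 0.0, d)
    u = (theta[..., None] - pop.preferred_angles) / pop.spacing
    f = tuning_rate(pop.tuning, 0.0, u)
    return np.where(np.abs(u) <= np.pi, f, pop.tuning.baseline)


def population_derivatives(pop: Population, theta) -> np.ndarray:
    """df_k/dtheta evaluated at theta; shape ``theta.shape + (N,)``."""
    theta = np.asarray(theta, dtype=float)
    if pop.geometry == "circular":
        d = theta[..., None] - pop.preferred_angles
        return tuning_derivative(pop.tuning, 0.0, d)
    u = (theta[..., None] - pop.preferred_angles) / pop.spacing
    g = tuning_derivative(pop.tuning, 0.0, u) / pop.spacing
    return np.where(np.abs(u) <= np.pi, g, 0.0)


def sample_responses(
    pop: Population,
    noise: NoiseSpec,
    theta: float,
    n_trials: int,
    seed,
) -> np.ndarray:
    """Sample an (n_trials, N) response matrix at a fixed stimulus angle.

    Gaussian noise returns rates ``f_k(theta) + sigma*nu``; Poisson noise
    returns integer spike counts ``n_k ~ Poisson(T f_k(theta))`` (decoders
    consume counts together with the window T carried by the NoiseSpec).
    The same seed always yields the identical matrix.
    """
    if n_trials < 1:
        raise ConfigurationError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    f = population_rates(pop, float(theta))
    if noise.kind == "gaussian":
        return f + noise.sigma * rng.standard_normal((n_trials, pop.n_neurons))
    if np.any(f < 0):
        raise ConfigurationError("poisson noise requires nonnegative tuning values")
    lam = np.broadcast_to(noise.window * f, (n_trials, pop.n_neurons))
    return rng.poisson(lam).astype(float)
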