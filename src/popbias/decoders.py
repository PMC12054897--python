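"""Stimulus decoders: population vector, maximum likelihood, Bayesian mean.

All three estimators operate on a single-trial response vector ``r`` (or,
vectorized, on an (n_trials, N) matrix).  The ML and Bayesian decoders share
a grid-based likelihood: the log likelihood is evaluated on a finely spaced
array of candidate stimuli covering one full period, the ML estimate is the
arg-max and the Bayesian (least-squares) estimate is the posterior mean under
a flat prior, computed in the circular (resultant-vector) form
``atan2(∫ sinθ P(θ|r) dθ, ∫ cosθ P(θ|r) dθ)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import NoiseSpec, Population, population_rates

__all__ = [
    "DecodeGrid",
    "Posterior",
    "DegenerateEstimateError",
    "pv_decode",
    "log_likelihood",
    "ml_decode",
    "posterior_on_grid",
    "bayes_decode",
    "decode_trials",
]

TWO_PI = 2.0 * np.pi

#: log-likelihood sentinel used inside vectorized matrices in place of -inf
#: (keeps 0 * log(0) products finite during the matrix products)
_NEG = -1e30


class DegenerateEstimateError(ValueError):
    """The estimate is undefined (zero resultant vector / all -inf likelihood)."""


@dataclass(frozen=True)
class DecodeGrid:
    """Uniform grid of candidate stimuli covering one period, half-open."""

    n_points: int = 10_000

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def resolution(self) -> float:
        return TWO_PI / self.n_points

    @property
    def candidates(self) -> np.ndarray:
        return self.resolution * np.arange(self.n_points)


@dataclass(frozen=True)
class Posterior:
    """Normalized posterior density on a decode grid (flat prior)."""

    grid: DecodeGrid
    log_values: np.ndarray  # unnormalized log posterior per candidate
    values: np.ndarray      # density; sums * resolution to 1

    def __post_init__(self) -> None:
        total = float(np.sum(self.values) * self.grid.resolution)
        if not np.isclose(total, 1.0, atol=1e-10):
            raise ValueError(f"posterior density must integrate to 1, got {total}")


def pv_decode(r, pop: Population):
    """Population-vector estimate: angle of ``Σ_k r_k (cos phi_k, sin phi_k)``.

    Accepts a single response vector (N,) or a trial matrix (n, N); returns a
    scalar or an array of angles in [0, 2*pi).
    """
    r = np.asarray(r, dtype=float)
    px = r @ np.cos(pop.preferred_angles)
    py = r @ np.sin(pop.preferred_angles)
    norm = np.hypot(px, py)
    if np.any(norm == 0.0):
        raise DegenerateEstimateError("population vector has zero length")
    return np.mod(np.arctan2(py, px), TWO_PI)


def _loglik_matrix(r: np.ndarray, pop: Population, noise: NoiseSpec, thetas: np.ndarray) -> np.ndarray:
    """(n_trials, n_candidates) log likelihood, up to per-trial constants.

    Gaussian: −Σ_k (f_k(θ) − r_k)² / (2σ²).  Poisson (r are counts over
    window T): Σ_k [r_k log(T f_k(θ)) − T f_k(θ)], with 0·log 0 := 0 and the
    ``_NEG`` sentinel standing in for −inf where a count is observed from a
    silent neuron.
    """
    F = population_rates(pop, thetas)  # (G, N)
    if noise.kind == "gaussian":
        s2 = noise.sigma**2
        if s2 == 0.0:
            s2 = np.finfo(float).tiny  # noiseless limit: delta-like likelihood
        quad = np.sum(F * F, axis=1)  # Σ f²(θ)
        return (r @ F.T - 0.5 * quad) / s2
    T = noise.window
    lam = T * F
    active = lam > 0
    log_lam = np.where(active, np.log(np.where(active, lam, 1.0)), 0.0)
    L = r @ log_lam.T - np.sum(lam, axis=1)
    # counts observed where the model rate is zero: impossible candidate
    bad = (r > 0).astype(float) @ (~active).T.astype(float) > 0
    return np.where(bad, _NEG, L)


def log_likelihood(r, pop: Population, noise: NoiseSpec, theta):
    """Log P(r | theta) up to an additive per-trial constant.

    ``theta`` may be a scalar or an array of candidate angles; Poisson
    candidates that are impossible (a count observed where T·f = 0) return
    −inf rather than raising.
    """
    single_r = np.asarray(r).ndim == 1
    single_th = np.ndim(theta) == 0
    r2 = np.atleast_2d(np.asarray(r, dtype=float))
    thetas = np.atleast_1d(np.asarray(theta, dtype=float))
    L = _loglik_matrix(r2, pop, noise, thetas)
    if noise.kind == "gaussian":
        # restore the per-trial -Σr²/2σ² term dropped inside the fast path,
        # giving the full -Σ(f-r)²/(2σ²) (0 and maximal at an exact match)
        s2 = noise.sigma**2 if noise.sigma > 0 else np.finfo(float).tiny
        L = L - np.sum(r2 * r2, axis=1, keepdims=True) / (2.0 * s2)
    L = np.where(L <= _NEG, -np.inf, L)
    if single_th:
        L = L[:, 0]
    if single_r:
        L = L[0]
    return float(L) if (single_r and single_th) else L


def ml_decode(r, pop: Population, noise: NoiseSpec, grid: DecodeGrid | None = None):
    """Maximum-likelihood estimate: grid arg-max of the log likelihood.

    Ties are broken deterministically toward the lowest-index candidate.
    """
    if grid is None:
        grid = DecodeGrid()
    single = np.asarray(r).ndim == 1
    r2 = np.atleast_2d(np.asarray(r, dtype=float))
    L = _loglik_matrix(r2, pop, noise, grid.candidates)
    if np.any(np.all(L <= _NEG, axis=1)):
        raise DegenerateEstimateError("all candidates have -inf likelihood")
    est = grid.candidates[np.argmax(L, axis=1)]
    return float(est[0]) if single else est


def posterior_on_grid(r, pop: Population, noise: NoiseSpec, grid: DecodeGrid | None = None) -> Posterior:
    """Flat-prior posterior density on the grid (max-subtracted for stability)."""
    if grid is None:
        grid = DecodeGrid()
    r2 = np.atleast_2d(np.asarray(r, dtype=float))
    if r2.shape[0] != 1:
        raise ValueError("posterior_on_grid takes a single response vector")
    L = _loglik_matrix(r2, pop, noise, grid.candidates)[0]
    W = np.exp(L - np.max(L))
    mass = np.sum(W) * grid.resolution
    if mass == 0.0 or not np.isfinite(mass):
        raise DegenerateEstimateError("posterior has zero normalization mass")
    return Posterior(grid, L, W / mass)


def bayes_decode(posterior: Posterior) -> float:
    """Posterior-mean (least-squares) estimate via the circular mean."""
    th = posterior.grid.candidates
    w = posterior.values
    cx = float(np.dot(w, np.cos(th)))
    sx = float(np.dot(w, np.sin(th)))
    if np.hypot(cx, sx) == 0.0:
        raise DegenerateEstimateError("posterior resultant vector has zero length")
    return float(np.mod(np.arctan2(sx, cx), TWO_PI))


def decode_trials(
    r,
    pop: Population,
    noise: NoiseSpec,
    decoders=("bayes",),
    grid: DecodeGrid | None = None,
    chunk: int = 512,
) -> dict[str, np.ndarray]:
    """Decode a trial matrix with one or more decoders sharing one likelihood.

    Returns ``{decoder_name: estimates}``; the likelihood matrix is computed
    once per chunk of trials and reused by the ML and Bayesian decoders, which
    makes large Monte-Carlo runs feasible.
    """
    if grid is None:
        grid = DecodeGrid()
    r = np.atleast_2d(np.asarray(r, dtype=float))
    n = r.shape[0]
    out = {d: np.empty(n) for d in decoders}
    need_grid = any(d in ("ml", "bayes") for d in decoders)
    if "pv" in decoders:
        out["pv"] = np.asarray(pv_decode(r, pop), dtype=float).reshape(n)
    if not need_grid:
        return out
    th = grid.candidates
    cos_th, sin_th = np.cos(th), np.sin(th)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        L = _loglik_matrix(r[lo:hi], pop, noise, th)
        if "ml" in decoders:
            if np.any(np.all(L <= _NEG, axis=1)):
                raise DegenerateEstimateError("all candidates have -inf likelihood")
            out["ml"][lo:hi] = th[np.argmax(L, axis=1)]
        if "bayes" in decoders:
            W = np.exp(L - np.max(L, axis=1, keepdims=True))
            cx = W @ cos_th
            sx = W @ sin_th
            if np.any(np.hypot(cx, sx) == 0.0):
                raise DegenerateEstimateError("posterior resultant vector has zero length")
            out["bayes"][lo:hi] = np.mod(np.arctan2(sx, cx), TWO_PI)
    return out
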