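import numpy as np
import pytest
from scipy.stats import poisson as poisson_dist

from popbias import (
    DecodeGrid,
    DegenerateEstimateError,
    NoiseSpec,
    TuningModel,
    bayes_decode,
    build_population,
    decode_trials,
    log_likelihood,
    ml_decode,
    population_rates,
    posterior_on_grid,
    pv_decode,
    sample_responses,
)


class TestPopulationVector:
    def test_single_contributing_neuron(self, default_pop):
        assert pv_decode([1.0, 0.0, 0.0, 0.0], default_pop) == pytest.approx(np.pi / 2)

    def test_symmetry_midpoint(self, default_pop):
        assert pv_decode([1.0, 1.0, 0.0, 0.0], default_pop) == pytest.approx(3 * np.pi / 4)

    def test_pure_cosine_noiseless_recovers_stimulus(self, pure_cosine_pop):
        # constant terms cancel over equally spaced angles; cosine terms
        # reproduce the stimulus exactly
        for theta in (0.7, 2.0, 5.5):
            r = population_rates(pure_cosine_pop, theta)
            assert pv_decode(r, pure_cosine_pop) == pytest.approx(theta, abs=1e-10)

    def test_zero_vector_degenerate(self, default_pop):
        with pytest.raises(DegenerateEstimateError):
            pv_decode([0.0, 0.0, 0.0, 0.0], default_pop)


class TestLogLikelihood:
    def test_gaussian_maximal_at_truth(self, default_pop, gaussian_noise):
        theta_star = 1.9
        r = population_rates(default_pop, theta_star)
        cand = np.append(np.linspace(0, 2 * np.pi, 512, endpoint=False), theta_star)
        L = log_likelihood(r, default_pop, gaussian_noise, cand)
        assert np.max(L) == pytest.approx(0.0, abs=1e-12)
        assert cand[np.argmax(L)] == pytest.approx(theta_star, abs=2 * np.pi / 512)

    def test_poisson_matches_pmf_up_to_constant(self):
        pop = build_population(1, tuning=TuningModel("rectified_cosine", threshold=-0.5))
        noise = NoiseSpec("poisson", window=1.5)
        r = np.array([2.0])
        cand = np.array([0.3, 1.0, 2.0])
        L = log_likelihood(r, pop, noise, cand)
        lam = 1.5 * population_rates(pop, cand)[:, 0]
        ref = poisson_dist.logpmf(2, lam)
        assert np.allclose(np.diff(L), np.diff(ref), atol=1e-10)

    def test_poisson_count_from_silent_neuron_is_neg_inf(self, narrow_pop):
        noise = NoiseSpec("poisson", window=2.0)
        # a count on the neuron at pi/2 while evaluating theta deep in another
        # neuron's exclusive region
        r = np.array([3.0, 0.0, 0.0, 0.0])
        assert log_likelihood(r, narrow_pop, noise, 3 * np.pi / 2) == -np.inf


class TestMLDecode:
    def test_noiseless_exact_match(self, default_pop, gaussian_noise, coarse_grid):
        theta = coarse_grid.candidates[700]
        r = population_rates(default_pop, theta)
        assert ml_decode(r, default_pop, gaussian_noise, coarse_grid) == pytest.approx(theta)

    def test_narrow_tuning_ambiguity_tie_break(self, narrow_pop, gaussian_noise, coarse_grid):
        """One active neuron: Θ and its mirror are equally likely; the tie is
        broken deterministically toward the lowest-index candidate."""
        phi = np.pi / 2
        theta = phi + 3 * coarse_grid.resolution
        r = population_rates(narrow_pop, theta)
        est = ml_decode(r, narrow_pop, gaussian_noise, coarse_grid)
        mirror = phi - 3 * coarse_grid.resolution
        assert min(abs(est - theta), abs(est - mirror)) < 1e-9
        est2 = ml_decode(r, narrow_pop, gaussian_noise, coarse_grid)
        assert est == est2

    def test_coarse_grid_agrees_with_fine_grid(self, default_pop, gaussian_noise):
        rng = np.random.default_rng(5)
        r = population_rates(default_pop, 2.5) + 0.1 * rng.standard_normal(4)
        coarse = ml_decode(r, default_pop, gaussian_noise, DecodeGrid(2000))
        fine = ml_decode(r, default_pop, gaussian_noise, DecodeGrid(40_000))
        assert abs(coarse - fine) <= 2 * np.pi / 2000


class TestPosterior:
    def test_density_integrates_to_one(self, default_pop, gaussian_noise, coarse_grid):
        r = population_rates(default_pop, 2.0) + 0.05
        post = posterior_on_grid(r, default_pop, gaussian_noise, coarse_grid)
        assert np.sum(post.values) * coarse_grid.resolution == pytest.approx(1.0, abs=1e-10)
        assert np.all(post.values >= 0)

    def test_large_noise_approaches_uniform(self, default_pop, coarse_grid):
        r = population_rates(default_pop, 2.0)
        post = posterior_on_grid(r, default_pop, NoiseSpec("gaussian", sigma=100.0), coarse_grid)
        assert np.max(post.values) / np.min(post.values) == pytest.approx(1.0, abs=1e-3)

    def test_small_noise_concentrates_at_truth(self, default_pop, coarse_grid):
        theta = coarse_grid.candidates[333]
        r = population_rates(default_pop, theta)
        post = posterior_on_grid(r, default_pop, NoiseSpec("gaussian", sigma=0.001), coarse_grid)
        assert bayes_decode(post) == pytest.approx(theta, abs=2 * coarse_grid.resolution)


class TestBayesDecode:
    def test_symmetric_posterior_returns_axis(self, narrow_pop, gaussian_noise, coarse_grid):
        """Single active neuron: the posterior is symmetric about the preferred
        angle, so the posterior mean sits exactly there (complete attraction)."""
        phi = np.pi / 2
        r = population_rates(narrow_pop, phi + 0.05)
        post = posterior_on_grid(r, narrow_pop, gaussian_noise, coarse_grid)
        assert bayes_decode(post) == pytest.approx(phi, abs=coarse_grid.resolution)

    def test_bimodal_equal_peaks_returns_midpoint(self, coarse_grid):
        phi = np.pi
        delta = 0.4
        th = coarse_grid.candidates
        vals = np.exp(-0.5 * ((th - (phi - delta)) / 0.05) ** 2) + np.exp(
            -0.5 * ((th - (phi + delta)) / 0.05) ** 2
        )
        vals /= np.sum(vals) * coarse_grid.resolution
        from popbias import Posterior

        post = Posterior(coarse_grid, np.log(vals + 1e-300), vals)
        assert bayes_decode(post) == pytest.approx(phi, abs=coarse_grid.resolution)


class TestDecoderProperties:
    def test_rotation_equivariance(self, gaussian_noise, coarse_grid):
        """Rotating stimulus and preferred angles together rotates every
        estimate by the same offset (offset chosen on the grid)."""
        from popbias import Population

        base = build_population(4)
        shift = 250 * coarse_grid.resolution
        shifted = Population(4, base.preferred_angles + shift, "circular", base.tuning)
        rng = np.random.default_rng(11)
        noise_draw = 0.1 * rng.standard_normal(4)
        theta = 2.0
        r = population_rates(base, theta) + noise_draw
        r_shift = population_rates(shifted, theta + shift) + noise_draw
        assert np.allclose(r, r_shift)  # tuning is relative: same responses
        for est_a, est_b in [
            (pv_decode(r, base), pv_decode(r_shift, shifted)),
            (
                ml_decode(r, base, gaussian_noise, coarse_grid),
                ml_decode(r_shift, shifted, gaussian_noise, coarse_grid),
            ),
            (
                bayes_decode(posterior_on_grid(r, base, gaussian_noise, coarse_grid)),
                bayes_decode(posterior_on_grid(r_shift, shifted, gaussian_noise, coarse_grid)),
            ),
        ]:
            d = np.angle(np.exp(1j * (est_b - est_a - shift)))
            assert abs(d) < 2 * coarse_grid.resolution

    def test_ml_equals_bayes_in_gaussian_limit(self):
        """Dense wide tuning, tiny noise: the posterior is Gaussian, so the
        mode (ML) and mean (Bayes) coincide."""
        pop = build_population(64, tuning=TuningModel("rectified_cosine", threshold=-0.5))
        noise = NoiseSpec("gaussian", sigma=0.01)
        grid = DecodeGrid(10_000)
        r = sample_responses(pop, noise, 2.7, 300, seed=13)
        est = decode_trials(r, pop, noise, decoders=("ml", "bayes"), grid=grid)
        close = np.abs(np.angle(np.exp(1j * (est["ml"] - est["bayes"])))) < 2 * grid.resolution
        assert np.mean(close) >= 0.99

    def test_pv_variance_exceeds_ml_variance(self, default_pop, gaussian_noise, coarse_grid):
        theta = 2.0
        r = sample_responses(default_pop, gaussian_noise, theta, 3000, seed=17)
        est = decode_trials(r, default_pop, gaussian_noise, decoders=("pv", "ml"), grid=coarse_grid)
        var = {d: np.var(np.angle(np.exp(1j * (est[d] - theta)))) for d in ("pv", "ml")}
        assert var["pv"] > var["ml"]
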