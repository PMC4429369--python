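"""Population construction, empirical likelihoods and Bayesian decoding."""

import numpy as np
import pytest

from nlifsim import (
    NoiseSpec,
    ResponsePattern,
    StimulusMap,
    bayes_posterior,
    build_population,
    estimate_likelihood,
    poisson_posterior,
    population_response,
)
from nlifsim.population import (
    default_stimulus_grid,
    likelihood_from_sampler,
)


# ---------------------------------------------------------------------------
# population construction


def test_population_spacing_covers_the_circle():
    pop = build_population(20)
    prefs = pop.preferred_stimuli
    assert prefs[0] == -180.0
    np.testing.assert_allclose(np.diff(prefs), 18.0)
    assert pop.size == 20


def test_single_neuron_population():
    pop = build_population(1)
    assert pop.preferred_stimuli.tolist() == [-180.0]
    with pytest.raises(ValueError):
        build_population(0)


def test_population_neurons_are_shifted_copies():
    pop = build_population(8, map_template=StimulusMap(sigma_s=25.0))
    for (p, m), pref in zip(pop.neurons, pop.preferred_stimuli):
        assert m.s_pref == pref
        assert m.sigma_s == 25.0
        assert p == pop.neurons[0][0]


# ---------------------------------------------------------------------------
# population responses


def test_response_zero_dev_is_deterministic(params):
    pop = build_population(10)
    a = population_response(pop, 0.0, NoiseSpec(), seed=1)
    b = population_response(pop, 0.0, NoiseSpec(), seed=2)
    np.testing.assert_array_equal(a.counts, b.counts)
    # matches the noise-free tuning value of each neuron
    from nlifsim import response_function

    for k, (p, m) in enumerate(pop.neurons):
        expected = response_function(p, np.array([m.current(0.0)]))[0]
        assert a.counts[k] == expected


def test_response_concentrates_near_preferred_stimulus(params):
    pop = build_population(20)
    pat = population_response(pop, 0.0, NoiseSpec.resistance_noise(0.05),
                              seed=3)
    prefs = pop.preferred_stimuli
    active = prefs[pat.counts > 0]
    assert pat.counts.sum() > 0
    assert np.all(np.abs(active) <= 72.0)
    # the best-tuned neurons dominate the total count
    near = np.abs(prefs) <= 36.0
    assert pat.counts[near].sum() >= 0.8 * pat.counts.sum()


def test_response_seed_sensitivity(params):
    pop = build_population(10)
    noise = NoiseSpec.resistance_noise(0.20)
    a = population_response(pop, 0.0, noise, seed=1)
    b = population_response(pop, 0.0, noise, seed=2)
    assert not np.array_equal(a.counts, b.counts)


def test_pattern_rejects_negative_counts():
    with pytest.raises(ValueError):
        ResponsePattern(np.array([1, -1]))


# ---------------------------------------------------------------------------
# empirical likelihood


def test_likelihood_columns_normalized_and_floored():
    rng = np.random.default_rng(0)

    def sampler(a, j, n):
        return rng.poisson(3.0 + a + j, size=n)

    lik = likelihood_from_sampler(sampler, 3, np.linspace(-10, 10, 5),
                                  repeats=200)
    sums = lik.table.sum(axis=2)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)
    assert np.all(lik.table > 0)  # smoothing floor everywhere
    assert lik.epsilon == pytest.approx(1.0 / 400)


def test_likelihood_zero_dev_is_point_mass(params):
    pop = build_population(4)
    grid = np.array([-30.0, 0.0, 30.0])
    lik = estimate_likelihood(pop, NoiseSpec(), grid, repeats=50, seed=0)
    # every column concentrates on the deterministic count (smoothing aside)
    from nlifsim import response_function

    top = lik.table.max(axis=2)
    assert np.all(top > 0.5)
    for a, (p, m) in enumerate(pop.neurons):
        expected = response_function(p, np.asarray(m.current(grid)))
        np.testing.assert_array_equal(np.argmax(lik.table[a], axis=1), expected)


def test_likelihood_means_match_tuning_statistics(params):
    """Cross-check: expected counts under the estimated likelihood agree
    with independently simulated tuning-curve means within 3 SE."""
    from nlifsim import noisy_tuning_curve

    pop = build_population(1, map_template=StimulusMap(s_pref=0.0))
    noise = NoiseSpec.resistance_noise(0.10)
    grid = np.array([-20.0, 0.0, 20.0])
    repeats = 80
    lik = estimate_likelihood(pop, noise, grid, repeats=repeats, seed=10)
    rates = lik.mean_rates()[0]
    tc = noisy_tuning_curve(pop.neurons[0][0], pop.neurons[0][1],
                            stimuli=grid, noise=noise, trials=80, seed=99)
    se = tc.sd_activity / np.sqrt(80)
    # smoothing shifts the expectation by at most eps * cmax
    slack = 3 * se + lik.epsilon * (lik.max_count + 1) ** 2 / 2 + 0.5
    assert np.all(np.abs(rates - tc.mean_activity) < slack)


# ---------------------------------------------------------------------------
# Bayesian decoding


def test_uniform_likelihood_gives_uniform_posterior():
    def sampler(a, j, n):
        return np.full(n, 2)  # same counts at every stimulus

    grid = np.linspace(-180, 180, 20, endpoint=False)
    lik = likelihood_from_sampler(sampler, 1, grid, repeats=10)
    post = bayes_posterior(lik, ResponsePattern(np.array([2])))
    np.testing.assert_allclose(post.posterior, 1.0 / 20, atol=1e-12)


def test_posterior_normalization_and_prior_invariance():
    rng = np.random.default_rng(5)

    def sampler(a, j, n):
        return rng.poisson(1.0 + 5 * np.exp(-(j - 10) ** 2 / 8.0), size=n)

    grid = np.linspace(-180, 180, 21)
    lik = likelihood_from_sampler(sampler, 2, grid, repeats=300)
    pat = ResponsePattern(np.array([4, 4]))
    post = bayes_posterior(lik, pat)
    assert post.posterior.sum() == pytest.approx(1.0, abs=1e-12)
    # flat-prior Bayes: a constant factor on the likelihood cancels
    ll = lik.log_likelihood(pat)
    shifted = np.exp(ll + 7.0 - (ll + 7.0).max())
    shifted /= shifted.sum()
    np.testing.assert_allclose(shifted, post.posterior, atol=1e-12)


def test_poisson_posterior_flat_for_constant_rates():
    grid = np.linspace(-180, 180, 30, endpoint=False)
    rates = np.full((1, 30), 4.0)
    post = poisson_posterior(rates, ResponsePattern(np.array([4])), grid)
    np.testing.assert_allclose(post.posterior, 1.0 / 30, atol=1e-12)


def test_poisson_posterior_mode_matches_brute_force():
    """Cosine-bump rates, pattern = rounded rates at s*=30 degrees."""
    grid = np.linspace(-180, 180, 120, endpoint=False)
    prefs = np.linspace(-180, 180, 20, endpoint=False)
    rates = np.array([10 * np.maximum(np.cos(np.radians(grid - p)), 0.0) ** 2
                      for p in prefs]) + 0.1
    s_true = 30.0
    j_true = int(np.argmin(np.abs(grid - s_true)))
    pattern = ResponsePattern(np.round(rates[:, j_true]).astype(int))
    post = poisson_posterior(rates, pattern, grid)
    # independent brute-force grid maximization of the Poisson likelihood
    from scipy.stats import poisson as poisson_dist

    ll = np.array([poisson_dist.logpmf(pattern.counts, rates[:, j]).sum()
                   for j in range(grid.size)])
    assert np.argmax(post.posterior) == np.argmax(ll)
    assert abs(grid[np.argmax(post.posterior)] - s_true) <= 3.01


def test_empirical_decoder_converges_to_poisson_analytic():
    """Counts generated as Poisson draws: the empirical decoder must agree
    with the closed form (total variation < 0.02 at 1e4 repeats)."""
    rng = np.random.default_rng(17)
    grid = np.linspace(-60, 60, 25)
    prefs = np.array([-40.0, -20.0, 0.0, 20.0, 40.0])
    rates = 8.0 * np.exp(-((grid[None, :] - prefs[:, None]) ** 2)
                         / (2 * 20.0**2)) + 0.2

    def sampler(a, j, n):
        return rng.poisson(rates[a, j], size=n)

    lik = likelihood_from_sampler(sampler, 5, grid, repeats=10_000)
    pattern = ResponsePattern(rng.poisson(rates[:, 12]))
    emp = bayes_posterior(lik, pattern).posterior
    ana = poisson_posterior(rates, pattern, grid, rate_floor=1e-12).posterior
    tv = 0.5 * np.abs(emp - ana).sum()
    assert tv < 0.02


def test_pattern_length_mismatch_raises():
    def sampler(a, j, n):
        return np.zeros(n, dtype=int)

    lik = likelihood_from_sampler(sampler, 2, np.linspace(0, 1, 3), repeats=5)
    with pytest.raises(ValueError):
        bayes_posterior(lik, ResponsePattern(np.array([0, 0, 0])))


def test_larger_population_decodes_more_sharply(params):
    """Doubling the population size does not widen the posterior: decoding
    uncertainty shrinks (or at worst stays) as more neurons contribute."""
    grid = default_stimulus_grid(50)
    noise = NoiseSpec.resistance_noise(0.10)
    mean_sigma = {}
    for n in (20, 40):
        pop = build_population(n)
        lik = estimate_likelihood(pop, noise, grid, repeats=60, seed=4)
        sigs = []
        for snap in range(6):
            pat = population_response(pop, 0.0, noise, seed=900 + snap)
            sigs.append(bayes_posterior(lik, pat).gauss_sigma)
        mean_sigma[n] = np.mean(sigs)
    assert mean_sigma[40] <= mean_sigma[20] * 1.05
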