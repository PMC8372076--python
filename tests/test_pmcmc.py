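"""Dirichlet-multinomial observation model, HMM simulator, particle filter
and particle-MCMC machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats

import kdrpop as k
from kdrpop._filter import dm_logpmf_kernel
from kdrpop.io import SampleSeries
from kdrpop.selection import SelectionParams, hwe_proportions, step_allele_freq


class TestDirichletMultinomial:
    def test_single_draw_equals_base_probability(self):
        for A in (0.1, 1.0, 57.0):
            ll = k.dirichlet_multinomial_logpmf((1, 0, 0), (0.2, 0.3, 0.5), A)
            assert ll == pytest.approx(np.log(0.2), abs=1e-12)

    def test_large_A_limit_is_multinomial(self):
        counts = np.array([7, 12, 21])
        probs = np.array([0.2, 0.3, 0.5])
        ll = k.dirichlet_multinomial_logpmf(counts, probs, 1e9)
        ll_mult = float(stats.multinomial.logpmf(counts, counts.sum(), probs))
        assert ll == pytest.approx(ll_mult, abs=1e-6)

    @pytest.mark.parametrize("counts,probs,A", [
        ((1, 1, 0), (0.5, 0.5, 0.0), 2.0),
        ((2, 0, 1), (0.3, 0.3, 0.4), 0.7),
        ((1, 1, 1), (0.2, 0.5, 0.3), 5.0),
    ])
    def test_matches_polya_urn_enumeration(self, counts, probs, A):
        # brute-force sum of sequential Polya urn probabilities over all
        # orderings of the n <= 3 draws
        probs_f = np.maximum(np.array(probs, dtype=float), 1e-12)
        alpha = A * probs_f / probs_f.sum()
        seq = list(itertools.chain.from_iterable(
            [i] * c for i, c in enumerate(counts)))
        total = 0.0
        for perm in set(itertools.permutations(seq)):
            prob, seen = 1.0, np.zeros(3)
            for j, cls in enumerate(perm):
                prob *= (alpha[cls] + seen[cls]) / (alpha.sum() + j)
                seen[cls] += 1
            total += prob
        ll = k.dirichlet_multinomial_logpmf(counts, probs, A)
        assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_kernel_agrees_with_scipy_wrapper(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 30, 3).astype(float)
            p = rng.dirichlet(np.ones(3))
            A = float(rng.uniform(0.05, 50))
            ours = dm_logpmf_kernel(counts[0], counts[1], counts[2],
                                    p[0], p[1], p[2], A)
            ref = k.dirichlet_multinomial_logpmf(counts, p, A)
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_nonpositive_A_rejected(self):
        with pytest.raises(ValueError):
            k.dirichlet_multinomial_logpmf((1, 0, 0), (0.5, 0.3, 0.2), 0.0)


class TestSimulateHMM:
    def test_fixed_seed_is_reproducible(self):
        params = k.HMMParams(s=0.1, h=0.3, R0=0.2, A=4.0, Ne=300)
        a = k.simulate_hmm(params, [20, 0, 30, 10], seed=7)
        b = k.simulate_hmm(params, [20, 0, 30, 10], seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1].counts, b[1].counts)
        assert a[1].months == b[1].months

    def test_zero_sample_months_emit_no_observation(self):
        params = k.HMMParams(s=0.1, h=0.3, R0=0.2, A=4.0, Ne=300)
        _, series = k.simulate_hmm(params, [20, 0, 30, 0, 10], seed=1)
        assert len(series) == 3
        assert series.t.tolist() == [0, 2, 4]

    def test_all_noise_off_fluctuates_around_R0_only_by_sampling(self):
        params = k.HMMParams(s=0.0, h=0.5, R0=0.3, A=1e9, Ne=10**9)
        _, series = k.simulate_hmm(params, np.full(40, 100), seed=2)
        pooled = series.resistance_allele_counts().sum() / (2 * series.n.sum())
        se = np.sqrt(0.3 * 0.7 / (2 * series.n.sum()))
        assert abs(pooled - 0.3) < 4 * se

    def test_mean_tracks_deterministic_trajectory(self):
        params = k.HMMParams(s=0.25, h=0.2, R0=0.15, A=50.0, Ne=5000)
        n_reps, horizon = 200, 24
        freqs = np.empty((n_reps, horizon))
        for r in range(n_reps):
            _, series = k.simulate_hmm(params, np.full(horizon, 100),
                                       seed=100 + r)
            freqs[r] = series.resistance_freq()
        det = k.simulate_deterministic(
            SelectionParams(0.25, 0.2, 0.15), horizon - 1).freqs
        mc_se = freqs.std(axis=0, ddof=1) / np.sqrt(n_reps)
        assert (np.abs(freqs.mean(axis=0) - det) < 4 * mc_se + 0.01).all()


def _grid_forward_loglik(series, params):
    """Exact HMM likelihood with the latent frequency discretized on the
    2*Ne+1 Wright-Fisher grid (independent oracle for the particle filter)."""
    two_ne = 2 * params.Ne
    grid = np.arange(two_ne + 1) / two_ne
    pd = np.array([step_allele_freq(p, params.s, params.h) for p in grid])
    T = stats.binom.pmf(np.arange(two_ne + 1)[None, :], two_ne, pd[:, None])
    ll = k.dirichlet_multinomial_logpmf(series.counts[0],
                                        hwe_proportions(params.R0), params.A)
    alpha = stats.binom.pmf(np.arange(two_ne + 1), two_ne,
                            step_allele_freq(params.R0, params.s, params.h))
    t_cur = 1
    for j in range(1, len(series)):
        while t_cur < series.t[j]:
            alpha = alpha @ T
            t_cur += 1
        obs = np.array([k.dirichlet_multinomial_logpmf(
            series.counts[j], hwe_proportions(p), params.A) for p in grid])
        m = obs.max()
        alpha = alpha * np.exp(obs - m)
        ll += m + np.log(alpha.sum())
        alpha = alpha / alpha.sum()
    return ll


class TestParticleFilter:
    def test_single_month_collapses_to_exact_pmf(self):
        params = k.HMMParams(s=0.2, h=0.2, R0=0.25, A=5.0, Ne=10**9)
        _, series = k.simulate_hmm(params, [40], seed=4)
        exact = k.dirichlet_multinomial_logpmf(
            series.counts[0], hwe_proportions(0.25), 5.0)
        for n_particles in (2, 17, 400):
            assert k.particle_loglik(series, params, n_particles,
                                     seed=0) == pytest.approx(exact, abs=1e-9)

    def test_fixed_seed_is_deterministic(self, benchmark_series):
        truth, _, series = benchmark_series
        a = k.particle_loglik(series, truth, 100, seed=12)
        b = k.particle_loglik(series, truth, 100, seed=12)
        assert a == b

    def test_variance_decreases_with_particle_count(self, benchmark_series):
        truth, _, series = benchmark_series
        short = SampleSeries(months=series.months[:30],
                             counts=series.counts[:30])
        small = [k.particle_loglik(short, truth, 100, seed=i)
                 for i in range(30)]
        large = [k.particle_loglik(short, truth, 1000, seed=i)
                 for i in range(30)]
        assert np.var(large) < np.var(small)

    def test_matches_grid_forward_oracle(self):
        # tiny instance: 3 time points, 51-point latent grid (Ne = 25)
        params = k.HMMParams(s=0.2, h=0.3, R0=0.3, A=8.0, Ne=25)
        rng_sizes = np.array([30, 0, 25, 0, 0, 35])
        _, series = k.simulate_hmm(params, rng_sizes, seed=6)
        assert len(series) == 3
        exact = _grid_forward_loglik(series, params)
        reps = [k.particle_loglik(series, params, 2000, seed=i)
                for i in range(30)]
        mc_se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - exact) < 3 * mc_se + 1e-3


class TestRunPMCMC:
    def test_prior_only_chain_samples_the_prior(self):
        cfg = k.PMCMCConfig(n_particles=10, n_iterations=8000, burn_in=1000,
                            thin=1, seed=3, store_paths=False)
        draws = k.run_pmcmc(None, cfg)
        means = draws.draws.mean(axis=0)
        # Beta(1,1) prior mean is 0.5 for s, h, R0
        assert np.allclose(means[:3], 0.5, atol=0.07)
        assert 0 < draws.acceptance_rate < 1

    def test_fixed_seed_gives_identical_chain(self):
        params = k.HMMParams(s=0.3, h=0.2, R0=0.3, A=10.0, Ne=200)
        _, series = k.simulate_hmm(params, np.full(8, 30), seed=5)
        cfg = k.PMCMCConfig(n_particles=50, n_iterations=300, burn_in=100,
                            thin=2, seed=9, ml_maxfev=30, store_paths=False)
        a = k.run_pmcmc(series, cfg)
        b = k.run_pmcmc(series, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.acceptance_rate == b.acceptance_rate

    def test_draws_stay_inside_prior_support(self):
        params = k.HMMParams(s=0.3, h=0.2, R0=0.3, A=10.0, Ne=200)
        _, series = k.simulate_hmm(params, np.full(8, 30), seed=5)
        cfg = k.PMCMCConfig(n_particles=50, n_iterations=400, burn_in=100,
                            thin=1, seed=2, ml_maxfev=30, store_paths=True)
        draws = k.run_pmcmc(series, cfg)
        assert (draws.draws[:, :3] > 0).all() and (draws.draws[:, :3] < 1).all()
        assert (draws.draws[:, 3] > 0).all()
        assert draws.latent_paths is not None
        assert draws.latent_paths.shape == (len(draws.draws),
                                            int(series.t[-1]) + 1)
        assert ((draws.latent_paths >= 0) & (draws.latent_paths <= 1)).all()


class TestSummarize:
    def test_identical_draws_give_zero_width(self):
        d = k.PosteriorDraws(draws=np.tile([0.2, 0.3, 0.4, 5.0], (50, 1)),
                             logliks=np.zeros(50), acceptance_rate=0.3)
        summary, bands = k.summarize_posterior(d)
        assert (summary.ci_low == summary.ci_high).all()
        np.testing.assert_allclose(summary["mean"], summary.ci_low,
                                   rtol=1e-12)
        assert bands is None

    def test_interval_endpoints_match_sorted_quantiles(self):
        rng = np.random.default_rng(1)
        draws = rng.uniform(size=(400, 4)) + 0.01
        d = k.PosteriorDraws(draws=draws, logliks=np.zeros(400),
                             acceptance_rate=0.3)
        summary, _ = k.summarize_posterior(d, level=0.9)
        for j in range(4):
            assert summary.ci_low[j] == pytest.approx(
                np.quantile(draws[:, j], 0.05))
            assert summary.ci_high[j] == pytest.approx(
                np.quantile(draws[:, j], 0.95))

    def test_genotype_bands_are_quantiles_of_mapped_paths(self):
        rng = np.random.default_rng(2)
        paths = rng.uniform(size=(200, 5))
        d = k.PosteriorDraws(draws=rng.uniform(size=(200, 4)) + 0.01,
                             logliks=np.zeros(200), acceptance_rate=0.3,
                             latent_paths=paths, start=(2003, 1))
        _, bands = k.summarize_posterior(d)
        rr = paths[:, 2] ** 2
        assert bands.RR_low[2] == pytest.approx(np.quantile(rr, 0.025))
        assert bands.RR_high[2] == pytest.approx(np.quantile(rr, 0.975))
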