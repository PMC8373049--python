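"""Tests for the Metropolis-within-Gibbs sampler and posterior summaries.

The deeper checks compare the sampler against independent oracles: a
hand-normalized two-term ratio for single-photon tag draws, closed-form
Dirichlet-categorical conjugacy for the weights, a dense-grid posterior for
the single-photon lifetime update, and exhaustive enumeration of the
marginal tag distribution (with the lifetimes integrated out numerically)
on a tiny trace.
"""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from photontau import (
    IRFModel,
    MixtureState,
    PhotonTrace,
    PosteriorSamples,
    Priors,
    SamplerSettings,
    emg_log_density,
    run_mcmc,
    sample_lifetimes,
    sample_tags,
    sample_weights,
    summarize,
)


class TestSampleTags:
    def test_degenerate_weights_pin_all_tags(self, tiny_trace, irf):
        state = MixtureState(np.array([1.0, 0.1]), np.array([1.0, 0.0]),
                             np.zeros(3, dtype=np.int64))
        rng = np.random.default_rng(0)
        tags = sample_tags(state, tiny_trace, irf, rng)
        assert np.all(tags == 0)

    def test_equal_components_give_uniform_tags(self, irf):
        trace = PhotonTrace(np.full(4000, 2.0), pulse_period=25.0)
        m = 4
        state = MixtureState(np.full(m, 0.5), np.full(m, 1.0 / m),
                             np.zeros(4000, dtype=np.int64))
        tags = sample_tags(state, trace, irf, np.random.default_rng(1))
        counts = np.bincount(tags, minlength=m)
        sd = np.sqrt(4000 * (1 / m) * (1 - 1 / m))
        assert np.all(np.abs(counts - 1000) < 4 * sd)

    def test_single_photon_matches_normalized_ratio(self, irf):
        """K=1, M=2: empirical tag-1 frequency over 1e5 draws matches the
        hand-normalized two-term posterior ratio within 3 SE."""
        trace = PhotonTrace(np.array([5.0]), pulse_period=25.0)
        w = np.array([0.4, 0.6])
        lams = np.array([1.0, 0.1])
        log_terms = np.log(w) + np.array(
            [emg_log_density(5.0, lam, irf) for lam in lams]
        )
        p0 = 1.0 / (1.0 + np.exp(log_terms[1] - log_terms[0]))
        state = MixtureState(lams, w, np.zeros(1, dtype=np.int64))
        rng = np.random.default_rng(2)
        n = 100_000
        hits = sum(
            int(sample_tags(state, trace, irf, rng)[0] == 0) for _ in range(n)
        )
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs(hits / n - p0) < 3 * se


class TestSampleWeights:
    def test_no_data_recovers_symmetric_prior_mean(self):
        priors = Priors(concentration=2.0, truncation=4)
        rng = np.random.default_rng(3)
        draws = np.array([
            sample_weights(np.empty(0, dtype=np.int64), priors, rng)
            for _ in range(20_000)
        ])
        # each coordinate has prior mean 1/M
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - 0.25) < 3 * se)

    def test_conjugate_posterior_mean_closed_form(self):
        # counts (3, 1), alpha = 2, M = 2: E[pi_1] = (1 + 3) / (2 + 4) = 2/3
        priors = Priors(concentration=2.0, truncation=2)
        tags = np.array([0, 0, 0, 1], dtype=np.int64)
        rng = np.random.default_rng(4)
        draws = np.array([sample_weights(tags, priors, rng)[0] for _ in range(20_000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.0 / 3.0) < 3 * se

    def test_simplex_constraint(self):
        priors = Priors(truncation=20)
        rng = np.random.default_rng(5)
        w = sample_weights(np.array([2, 2, 7], dtype=np.int64), priors, rng)
        assert w.shape == (20,)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(w > 0)


class TestSampleLifetimes:
    def test_unoccupied_components_recover_prior(self, irf):
        priors = Priors(gamma_shape=2.0, gamma_rate=0.5, truncation=2)
        trace = PhotonTrace(np.array([3.0]), pulse_period=25.0)
        settings = SamplerSettings(proposal_scale=0.5, seed=0)
        state = MixtureState(np.array([0.3, 1.0]), np.array([0.5, 0.5]),
                             np.zeros(1, dtype=np.int64))
        rng = np.random.default_rng(6)
        draws = []
        for _ in range(20_000):
            lams, _ = sample_lifetimes(state, trace, priors, irf, settings, rng)
            draws.append(lams[1])  # component 1 holds no photons
        draws = np.asarray(draws)
        want = priors.gamma_shape / priors.gamma_rate
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - want) < 3 * se

    def test_single_photon_chain_matches_grid_posterior(self):
        """One photon at dt = 2 with Gamma(1,1) prior: the MH chain's
        lambda distribution matches the grid-normalized prior x likelihood
        (sup-CDF distance below a loose chain-noise tolerance)."""
        irf = IRFModel(0.0, 0.1)
        priors = Priors(gamma_shape=1.0, gamma_rate=1.0, truncation=2)
        trace = PhotonTrace(np.array([2.0]), pulse_period=25.0)
        settings = SamplerSettings(proposal_scale=0.8, seed=0)
        rng = np.random.default_rng(7)
        state = MixtureState(np.array([1.0, 1.0]), np.array([1.0, 0.0]),
                             np.zeros(1, dtype=np.int64))
        draws = []
        for i in range(60_000):
            lams, _ = sample_lifetimes(state, trace, priors, irf, settings, rng)
            state = MixtureState(lams, state.weights, state.tags)
            if i % 5 == 0:
                draws.append(lams[0])
        draws = np.sort(np.asarray(draws)[400:])

        grid = np.linspace(1e-4, 40.0, 20_000)
        log_post = -grid + np.array([emg_log_density(2.0, g, irf) for g in [grid]])[0]
        post = np.exp(log_post - log_post.max())
        cdf = np.cumsum(post)
        cdf /= cdf[-1]
        emp = np.searchsorted(draws, grid, side="right") / draws.size
        assert np.max(np.abs(emp - cdf)) < 0.03

    def test_tiny_proposal_scale_always_accepts(self, irf):
        priors = Priors()
        trace = PhotonTrace(np.array([1.0, 2.0, 3.0]), pulse_period=25.0)
        settings = SamplerSettings(proposal_scale=1e-9, seed=0)
        state = MixtureState(np.full(priors.truncation, 0.5),
                             np.full(priors.truncation, 1.0 / priors.truncation),
                             np.zeros(3, dtype=np.int64))
        rng = np.random.default_rng(8)
        for _ in range(200):
            _, accepted = sample_lifetimes(state, trace, priors, irf, settings, rng)
            assert accepted[0]


def _log_subset_marginal(dts, priors, irf):
    """Numerically integrate Gamma prior x EMG likelihood over lambda."""
    def log_f(lam):
        lp = (priors.gamma_shape * np.log(priors.gamma_rate)
              - gammaln(priors.gamma_shape)
              + (priors.gamma_shape - 1.0) * np.log(lam)
              - priors.gamma_rate * lam)
        return lp + sum(emg_log_density(dt, lam, irf) for dt in dts)

    c = max(log_f(x) for x in np.geomspace(1e-3, 50, 200))
    val, _ = quad(lambda x: np.exp(log_f(x) - c), 0, np.inf, limit=400)
    return c + np.log(val)


class TestCollapsedConsistency:
    def test_joint_tag_distribution_matches_enumeration(self, irf):
        """K = 3, M = 2 toy: the sampler's marginal distribution over the
        2^3 tag assignments matches exhaustive enumeration with lambdas
        integrated out by quadrature, within 3 batch-means SE."""
        dts = (0.6, 1.8, 9.0)
        trace = PhotonTrace(np.array(dts), pulse_period=25.0)
        priors = Priors(concentration=1.0, truncation=2)
        a = priors.concentration / priors.truncation

        # enumeration oracle
        log_probs = {}
        marg_cache = {}
        for s in itertools.product(range(2), repeat=3):
            counts = np.bincount(s, minlength=2)
            log_p = float(np.sum(gammaln(a + counts) - gammaln(a)))
            for m in range(2):
                subset = tuple(dts[k] for k in range(3) if s[k] == m)
                if subset:
                    if subset not in marg_cache:
                        marg_cache[subset] = _log_subset_marginal(subset, priors, irf)
                    log_p += marg_cache[subset]
            log_probs[s] = log_p
        z = np.logaddexp.reduce(list(log_probs.values()))
        want = {s: np.exp(v - z) for s, v in log_probs.items()}

        settings = SamplerSettings(n_sweeps=42_000, burn_in=2000, thinning=4,
                                   proposal_scale=0.8, seed=9, adapt=True,
                                   keep_tags=True)
        samples = run_mcmc(trace, priors, irf, settings)
        tags = samples.tags
        keys = list(want)
        codes = tags[:, 0] * 4 + tags[:, 1] * 2 + tags[:, 2]
        n = codes.size
        n_batches = 40
        batch = n // n_batches
        for s in keys:
            code = s[0] * 4 + s[1] * 2 + s[2]
            hit = (codes == code).astype(float)
            means = hit[: batch * n_batches].reshape(n_batches, batch).mean(axis=1)
            se = means.std(ddof=1) / np.sqrt(n_batches)
            assert abs(hit.mean() - want[s]) < 3 * se + 5e-3, (s, hit.mean(), want[s])


class TestRunMcmc:
    def test_prior_predictive_matches_direct_prior_sampling(self, irf):
        priors = Priors(concentration=1.0, gamma_shape=2.0, gamma_rate=0.8,
                        truncation=5)
        trace = PhotonTrace(np.empty(0), pulse_period=25.0)
        settings = SamplerSettings(n_sweeps=8000, burn_in=0, seed=10)
        samples = run_mcmc(trace, priors, irf, settings)
        assert np.all(samples.occupied_counts == 0)
        lam = samples.inverse_lifetimes.ravel()
        want_mean = priors.gamma_shape / priors.gamma_rate
        want_var = priors.gamma_shape / priors.gamma_rate**2
        assert abs(lam.mean() - want_mean) < 4 * np.sqrt(want_var / lam.size)
        w = samples.weights
        se = w.std(axis=0, ddof=1) / np.sqrt(w.shape[0])
        assert np.all(np.abs(w.mean(axis=0) - 0.2) < 4 * se)

    def test_deterministic_given_seed(self, irf):
        trace = PhotonTrace(np.array([0.5, 1.0, 4.0, 9.0]), pulse_period=25.0)
        settings = SamplerSettings(n_sweeps=300, burn_in=50, seed=11)
        a = run_mcmc(trace, Priors(), irf, settings)
        b = run_mcmc(trace, Priors(), irf, settings)
        assert np.array_equal(a.inverse_lifetimes, b.inverse_lifetimes)
        assert np.array_equal(a.occupied_counts, b.occupied_counts)
        assert np.array_equal(a.log_posteriors, b.log_posteriors)

    def test_retained_sweep_count(self, irf):
        trace = PhotonTrace(np.array([1.0, 2.0]), pulse_period=25.0)
        settings = SamplerSettings(n_sweeps=1000, burn_in=200, thinning=4, seed=12)
        samples = run_mcmc(trace, Priors(), irf, settings)
        assert samples.n_retained == 200

    def test_occupied_counts_match_distinct_tags(self, irf):
        trace = PhotonTrace(np.array([0.4, 1.1, 2.2, 8.0, 12.0]), pulse_period=25.0)
        settings = SamplerSettings(n_sweeps=400, burn_in=100, seed=13, keep_tags=True)
        samples = run_mcmc(trace, Priors(), irf, settings)
        for i in range(samples.n_retained):
            assert samples.occupied_counts[i] == np.unique(samples.tags[i]).size
            assert 1 <= samples.occupied_counts[i] <= min(
                trace.n_photons, samples.priors.truncation
            )

    def test_exchangeability_of_photon_order(self, acquisition):
        """Permuting microtimes leaves posterior summaries unchanged up to
        Monte-Carlo noise (tags are conditionally independent given the
        state)."""
        from photontau import SimConfig, simulate_trace

        period, irf = acquisition
        cfg = SimConfig(lifetimes=(4.0,), fractions=(1.0,), n_photons=400,
                        irf=irf, pulse_period=period, seed=14)
        trace, _ = simulate_trace(cfg)
        perm = np.random.default_rng(15).permutation(trace.n_photons)
        shuffled = PhotonTrace(trace.microtimes[perm], trace.pulse_period)
        settings = SamplerSettings(n_sweeps=3000, burn_in=1000, seed=16)
        rep_a = summarize(run_mcmc(trace, Priors(), irf, settings), trace)
        rep_b = summarize(run_mcmc(shuffled, Priors(), irf, settings), shuffled)
        assert rep_a.modal_species_count == rep_b.modal_species_count
        np.testing.assert_allclose(
            rep_a.lifetime_estimates.mean, rep_b.lifetime_estimates.mean,
            rtol=0.1,
        )

    def test_single_photon_is_prior_dominated_and_flagged(self, irf):
        trace = PhotonTrace(np.array([2.0]), pulse_period=25.0)
        settings = SamplerSettings(n_sweeps=1500, burn_in=500, seed=17)
        samples = run_mcmc(trace, Priors(), irf, settings)
        report = summarize(samples, trace)
        assert report.low_information
        assert report.modal_species_count == 1
        assert report.lifetime_estimates.mean.size == 1

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SamplerSettings(n_sweeps=100, burn_in=100)
        with pytest.raises(ValueError):
            SamplerSettings(thinning=0)
        with pytest.raises(ValueError):
            SamplerSettings(proposal_scale=0.0)


class TestSummarize:
    def _make_samples(self, lam, counts, priors=None):
        lam = np.asarray(lam, dtype=float)
        counts = np.asarray(counts, dtype=np.int64)
        s, m = lam.shape
        totals = counts.sum(axis=1, keepdims=True)
        w = counts / np.where(totals > 0, totals, 1)
        return PosteriorSamples(
            inverse_lifetimes=lam,
            weights=w,
            counts=counts,
            occupied_counts=(counts > 0).sum(axis=1),
            log_posteriors=np.zeros(s),
            acceptance_rate=0.3,
            n_photons=int(counts.sum(axis=1)[0]) if s else 0,
            settings=SamplerSettings(n_sweeps=2, burn_in=0),
            priors=priors or Priors(truncation=max(m, 2)),
        )

    def test_point_mass_species_count(self):
        samples = self._make_samples(
            lam=[[1.0, 0.1, 0.5], [0.9, 0.11, 0.4]],
            counts=[[5, 5, 0], [4, 6, 0]],
        )
        trace = PhotonTrace(np.ones(10), pulse_period=25.0)
        report = summarize(samples, trace)
        assert report.species_count_posterior == {2: 1.0}
        assert report.modal_species_count == 2

    def test_relabeling_invariance(self):
        base = self._make_samples(
            lam=[[1.0, 0.1, 0.5], [0.1, 1.0, 0.5]],
            counts=[[5, 5, 0], [5, 5, 0]],
        )
        trace = PhotonTrace(np.ones(10), pulse_period=25.0)
        rep = summarize(base, trace)
        # both sweeps describe the same two species; sorted summaries match
        np.testing.assert_allclose(rep.lifetime_estimates.mean, [1.0, 10.0])
        assert np.all(rep.lifetime_estimates.ci_low
                      <= rep.lifetime_estimates.median)
        assert np.all(rep.lifetime_estimates.median
                      <= rep.lifetime_estimates.ci_high)

    def test_empty_chain_raises(self):
        samples = self._make_samples(lam=np.empty((0, 2)), counts=np.empty((0, 2)))
        trace = PhotonTrace(np.ones(2), pulse_period=25.0)
        with pytest.raises(RuntimeError):
            summarize(samples, trace)
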