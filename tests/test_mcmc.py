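"""Unit tests for the Metropolis–Hastings sampler and its diagnostics."""

import math

import numpy as np
import pytest

from il12sig import (
    ChainConfig,
    ChainResult,
    gelman_rubin,
    run_mcmc,
    summarize_posterior,
    tune_proposals,
)
from il12sig.mcmc import TuningError

UNBOUNDED = [(-math.inf, math.inf)]


def std_normal_loglik(x):
    return -0.5 * float(x[0]) ** 2


def psrf_oracle(samples, burn_in):
    """Independent transcription of the between/within-variance formula."""
    m, n_total, k = samples.shape
    post = samples[:, int(np.floor(burn_in * n_total)):, :]
    n = post.shape[1]
    out = np.empty(k)
    for p in range(k):
        chains = post[:, :, p]
        means = chains.mean(axis=1)
        w = np.mean([np.var(c, ddof=1) for c in chains])
        b = n * np.var(means, ddof=1)
        v_hat = (n - 1) / n * w + b / n
        out[p] = math.sqrt(v_hat / w)
    return out


class TestRunMcmc:
    def test_standard_normal_target_moments(self):
        config = ChainConfig(
            n_steps=20_000, init_center=(0.0,), init_dispersion=(5.0,), seed=42
        )
        result = run_mcmc(std_normal_loglik, config, UNBOUNDED)
        pooled = result.pooled()[:, 0]
        assert abs(pooled.mean()) < 0.05
        assert abs(pooled.std() - 1.0) < 0.05
        assert np.all(result.psrf < 1.2)

    def test_seed_determinism(self):
        config = ChainConfig(
            n_steps=2_000, init_center=(0.0,), init_dispersion=(5.0,), seed=7
        )
        r1 = run_mcmc(std_normal_loglik, config, UNBOUNDED)
        r2 = run_mcmc(std_normal_loglik, config, UNBOUNDED)
        assert np.array_equal(r1.samples, r2.samples)
        assert np.array_equal(r1.accept_fraction, r2.accept_fraction)

    def test_flat_target_accepts_nearly_everything(self):
        config = ChainConfig(
            n_steps=5_000, init_center=(0.5,), init_dispersion=(0.4,), seed=3
        )
        result = run_mcmc(
            lambda x: 0.0, config, [(0.0, 1.0)], proposal_sd=np.array([0.05])
        )
        assert np.all(result.accept_fraction > 0.8)
        pooled = result.pooled()[:, 0]
        # flat target over (0, 1): roughly uniform occupancy
        assert abs(pooled.mean() - 0.5) < 0.1

    def test_out_of_domain_start_raises(self):
        config = ChainConfig(
            n_steps=100, init_center=(0.0,), init_dispersion=(1.0,), seed=0
        )
        with pytest.raises(RuntimeError, match="starting point"):
            run_mcmc(lambda x: -math.inf, config, UNBOUNDED)


class TestTuneProposals:
    def test_reaches_target_acceptance(self):
        config = ChainConfig(
            n_steps=10, init_center=(0.0,), init_dispersion=(5.0,), seed=5
        )
        sd = tune_proposals(std_normal_loglik, config, UNBOUNDED, pilot_steps=2_000)
        rng = np.random.default_rng(123)
        from il12sig.mcmc import _run_chain

        _, _, acc = _run_chain(
            std_normal_loglik, np.array([0.0]), sd, 10_000, UNBOUNDED, rng
        )
        assert 0.15 <= acc <= 0.25

    def test_narrow_target_shrinks_huge_sd(self):
        config = ChainConfig(
            n_steps=10, init_center=(0.0,), init_dispersion=(1.0,), seed=5
        )
        sd = tune_proposals(
            std_normal_loglik,
            config,
            UNBOUNDED,
            initial_sd=np.array([500.0]),
            pilot_steps=1_000,
        )
        assert sd[0] < 500.0

    def test_flat_target_returns_initial_sd(self):
        config = ChainConfig(
            n_steps=10, init_center=(0.5,), init_dispersion=(0.4,), seed=5
        )
        sd = tune_proposals(
            lambda x: 0.0,
            config,
            [(-math.inf, math.inf)],
            initial_sd=np.array([0.25]),
            pilot_steps=200,
        )
        assert sd[0] == 0.25

    def test_tuning_failure_carries_acceptance(self):
        # an untunable pathological target: accept everything inside a point mass
        config = ChainConfig(
            n_steps=10, init_center=(0.0,), init_dispersion=(1.0,), seed=5
        )
        with pytest.raises(TuningError) as err:
            tune_proposals(
                std_normal_loglik,
                config,
                UNBOUNDED,
                initial_sd=np.array([1.0]),
                pilot_steps=50,
                max_rounds=1,
                tolerance=1e-6,
            )
        assert 0.0 <= err.value.last_acceptance <= 1.0


class TestGelmanRubin:
    def test_iid_chains_converge(self):
        rng = np.random.default_rng(0)
        samples = rng.standard_normal((3, 10_000, 2))
        psrf = gelman_rubin(samples, burn_in=0.0)
        assert np.all(psrf < 1.05)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        samples = np.stack(
            [rng.normal(0, 1, (500, 1)), rng.normal(10, 1, (500, 1))]
        )
        psrf = gelman_rubin(samples, burn_in=0.0)
        assert psrf[0] > 1.2

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(size=(4, 200, 3)) * [1.0, 2.0, 0.5] + [0, 1, -1]
        psrf = gelman_rubin(samples, burn_in=0.3)
        oracle = psrf_oracle(samples, burn_in=0.3)
        np.testing.assert_allclose(psrf, oracle, rtol=1e-10)

    def test_degenerate_chain_raises(self):
        samples = np.zeros((2, 50, 1))
        with pytest.raises(ValueError, match="degenerate"):
            gelman_rubin(samples, burn_in=0.0)


class TestSummarize:
    def _result_from_pooled(self, chain_a, chain_b):
        samples = np.array(chain_a + chain_b, dtype=float).reshape(2, -1, 1)
        logpost = -np.abs(samples[:, :, 0])  # peak nearest zero
        return ChainResult(
            samples=samples,
            logpost=logpost,
            accept_fraction=np.array([0.2, 0.2]),
            proposal_sd=np.array([1.0]),
            burn_in=0.0,
            psrf=np.array([1.0]),
        )

    def test_hand_counted_summary(self):
        result = self._result_from_pooled([-1.0, 1.0], [2.0, 3.0])
        s = summarize_posterior(result, burn_in=0.0, threshold=0.0, param=0)
        assert s.median == pytest.approx(1.5)
        assert s.tail_prob == pytest.approx(0.25)
        assert not s.significant

    def test_ml_value_is_highest_logpost_sample(self):
        result = self._result_from_pooled([-1.0, 0.5], [2.0, 3.0])
        s = summarize_posterior(result, burn_in=0.0, param=0)
        assert s.ml_value[0] == pytest.approx(0.5)  # peak of -|x| among samples

    def test_all_positive_samples(self):
        result = self._result_from_pooled([0.5, 1.0], [2.0, 3.0])
        s = summarize_posterior(result, burn_in=0.0, param=0)
        assert s.tail_prob == 0.0 and s.significant

    def test_symmetric_samples_tail_half(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4000)
        result = self._result_from_pooled(list(x[:2000]), list(x[2000:]))
        s = summarize_posterior(result, burn_in=0.0, param=0)
        assert s.tail_prob == pytest.approx(0.5, abs=0.03)

    def test_unconverged_requires_override(self):
        result = self._result_from_pooled([-1.0, 1.0], [2.0, 3.0])
        result.psrf = np.array([5.0])
        with pytest.raises(RuntimeError, match="not converged"):
            summarize_posterior(result, param=0)
        summarize_posterior(result, param=0, check_convergence=False)


class TestDetailedBalance:
    def test_three_state_frequencies_match_target(self):
        """Piecewise-flat target over three unit cells with known masses."""
        probs = np.array([0.5, 0.3, 0.2])
        log_p = np.log(probs)

        def loglik(x):
            return float(log_p[int(x[0])])

        config = ChainConfig(
            n_steps=40_000,
            n_chains=2,
            init_center=(1.5,),
            init_dispersion=(1.4,),
            seed=17,
        )
        result = run_mcmc(
            loglik, config, [(0.0, 3.0 - 1e-12)], proposal_sd=np.array([1.0])
        )
        pooled = result.pooled()[:, 0]
        states = np.floor(pooled).astype(int)
        freqs = np.bincount(states, minlength=3) / states.size
        # Monte-Carlo standard error per state from 10 batch means
        batches = np.array_split(states, 10)
        for s in range(3):
            batch_freqs = np.array([(b == s).mean() for b in batches])
            se = batch_freqs.std(ddof=1) / math.sqrt(len(batches))
            assert abs(freqs[s] - probs[s]) < 3 * se + 0.01
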