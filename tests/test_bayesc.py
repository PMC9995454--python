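"""Spike-slab Gibbs sampler, posterior summaries and the enumeration oracle."""

import numpy as np
import pytest
from scipy import stats

from bvsmap.bayesc import (
    BayesCPrior,
    MCMCConfig,
    PosteriorDraws,
    exact_pip_enumeration,
    gibbs_bayesc,
    summarize,
)


def fixed_hyper_prior(pi, s2b, s2e, strength=1e8):
    """Prior so concentrated the hyperparameters are effectively pinned."""
    return BayesCPrior(
        alpha1=pi * strength,
        alpha2=(1 - pi) * strength,
        df_beta=strength,
        scale_beta=s2b,
        df_eps=strength,
        scale_eps=s2e,
    )


def toy_problem(n=300, p=8, h2_one=0.2, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if p > 1:
        X[:, 1] += 0.8 * X[:, 0]  # some collinearity
    X -= X.mean(0)
    beta = np.zeros(p)
    beta[p // 2] = np.sqrt(h2_one / X[:, p // 2].var())
    y = X @ beta + rng.normal(0, np.sqrt(1 - h2_one), n)
    return X, y - y.mean()


class TestEnumerationOracle:
    def test_pi_zero_gives_zero_pips(self):
        X, y = toy_problem(50, 4)
        np.testing.assert_array_equal(
            exact_pip_enumeration(X, y, 0.0, 0.5, 1.0), np.zeros(4)
        )

    def test_single_snp_matches_two_model_bayes_factor(self):
        X, y = toy_problem(100, 1)
        pi, s2b, s2e = 0.3, 0.4, 1.0
        pip = exact_pip_enumeration(X, y, pi, s2b, s2e)[0]
        # closed form: two Gaussian marginal likelihoods
        n = len(y)
        c = float(X[:, 0] @ X[:, 0])
        b = float(X[:, 0] @ y)
        yy = float(y @ y)
        ll0 = -0.5 * (n * np.log(2 * np.pi * s2e) + yy / s2e)
        M = s2e + s2b * c
        ll1 = -0.5 * (
            n * np.log(2 * np.pi)
            + (n - 1) * np.log(s2e)
            + np.log(M)
            + (yy - s2b * b * b / M) / s2e
        )
        w1 = np.log(pi) + ll1
        w0 = np.log(1 - pi) + ll0
        expected = 1.0 / (1.0 + np.exp(w0 - w1))
        assert pip == pytest.approx(expected, abs=1e-12)

    def test_orthonormal_columns_factorize(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((80, 10))
        A -= A.mean(0)
        Q, _ = np.linalg.qr(A)
        y = rng.standard_normal(80)
        y -= y.mean()
        pi, s2b, s2e = 0.2, 0.5, 1.0
        pips = exact_pip_enumeration(Q, y, pi, s2b, s2e)
        # under orthonormal X the posterior factorizes: per-SNP two-model form
        for j in range(10):
            per = exact_pip_enumeration(Q[:, [j]], y, pi, s2b, s2e)[0]
            assert pips[j] == pytest.approx(per, abs=1e-6)

    def test_large_p_refused(self):
        X, y = toy_problem(30, 8)
        with pytest.raises(ValueError, match="p <= 15"):
            exact_pip_enumeration(np.tile(X, (1, 2)), y, 0.1, 0.1, 1.0)


class TestGibbsSampler:
    def test_matches_enumeration_on_toy(self):
        X, y = toy_problem(300, 8, h2_one=0.2, seed=1)
        pi, s2b, s2e = 0.1, 0.1, 0.8
        exact = exact_pip_enumeration(X, y, pi, s2b, s2e)
        draws = gibbs_bayesc(
            X,
            y,
            fixed_hyper_prior(pi, s2b, s2e),
            MCMCConfig(n_iter=22000, burn_in=2000, thin=1, seed=5),
        )
        pip = summarize(draws).pip
        assert np.abs(pip - exact).max() <= 0.02

    def test_deterministic_given_seed(self):
        X, y = toy_problem(100, 5)
        cfg = MCMCConfig(n_iter=400, burn_in=100, thin=2, seed=9)
        d1 = gibbs_bayesc(X, y, cfg=cfg)
        d2 = gibbs_bayesc(X, y, cfg=cfg)
        np.testing.assert_array_equal(d1.beta_values, d2.beta_values)
        np.testing.assert_array_equal(d1.delta_packed, d2.delta_packed)

    def test_no_signal_does_not_inflate_pips(self):
        # Null trait: inclusion stays at or below the prior non-null
        # proportion.  (With an informative sample the posterior pushes
        # null SNPs *below* the prior -- the Occam factor of the slab --
        # so the prior mean is a one-sided ceiling, and no SNP should
        # come anywhere near confident inclusion.)
        rng = np.random.default_rng(11)
        X = rng.standard_normal((500, 200))
        X -= X.mean(0)
        y = rng.standard_normal(500)
        y -= y.mean()
        prior = BayesCPrior()  # E[pi] = 1.1/100.1
        draws = gibbs_bayesc(
            X, y, prior, MCMCConfig(n_iter=6000, burn_in=1000, thin=1, seed=13)
        )
        summ = summarize(draws)
        assert summ.pip.mean() <= prior.prior_mean_pi + 0.005
        assert summ.pip.max() < 0.5

    def test_weak_data_pip_returns_to_prior(self):
        # In the weak-data limit (slab variance tiny relative to the
        # per-SNP sampling noise) the Bayes factor is ~1 and the PIP
        # reverts to the fixed prior inclusion probability.
        rng = np.random.default_rng(12)
        n, p = 100, 20
        X = rng.standard_normal((n, p))
        X -= X.mean(0)
        y = rng.standard_normal(n)
        y -= y.mean()
        pi = 0.2
        s2b = 1e-6
        draws = gibbs_bayesc(
            X, y, fixed_hyper_prior(pi, s2b, 1.0),
            MCMCConfig(n_iter=8000, burn_in=1000, thin=1, seed=14),
        )
        assert summarize(draws).pip.mean() == pytest.approx(pi, abs=0.02)

    def test_residual_consistency(self):
        X, y = toy_problem(150, 6, seed=2)
        draws = gibbs_bayesc(
            X, y, cfg=MCMCConfig(n_iter=50, burn_in=10, thin=1, seed=3)
        )
        # the incrementally updated residual must equal y - X beta recomputed
        beta_last = draws.beta_matrix()[-1]
        np.testing.assert_allclose(
            draws.final_residual, y - X @ beta_last, atol=1e-8
        )

    def test_variance_decomposition(self):
        rng = np.random.default_rng(17)
        n, p = 600, 40
        X = rng.binomial(2, 0.4, (n, p)).astype(float)
        X -= X.mean(0)
        beta = np.zeros(p)
        beta[[3, 17, 31]] = [0.3, -0.35, 0.3]
        g = X @ beta
        y = g + rng.normal(0, g.std(), n)  # ~50% heritability
        y -= y.mean()
        draws = gibbs_bayesc(
            X, y, cfg=MCMCConfig(n_iter=3000, burn_in=500, thin=2, seed=19)
        )
        summ = summarize(draws)
        explained = (X @ summ.post_mean_beta).var()
        total = draws.sigma2_eps_draws.mean() + explained
        assert total == pytest.approx(y.var(), rel=0.10)

    def test_h2_recovery_interval_coverage(self):
        # genomic variance share posterior should cover the simulated 0.5
        rng = np.random.default_rng(23)
        n, p = 500, 30
        hits = 0
        for rep in range(5):
            X = rng.binomial(2, 0.3, (n, p)).astype(float)
            X -= X.mean(0)
            beta = np.zeros(p)
            idx = rng.choice(p, 4, replace=False)
            beta[idx] = rng.standard_normal(4)
            g = X @ beta
            g *= np.sqrt(0.5) / g.std()
            y = g + rng.normal(0, np.sqrt(0.5), n)
            y -= y.mean()
            draws = gibbs_bayesc(
                X, y, cfg=MCMCConfig(n_iter=3000, burn_in=500, thin=2, seed=rep)
            )
            bm = draws.beta_matrix()
            shares = np.array(
                [(X @ b).var() for b in bm]
            ) / y.var()
            lo, hi = np.quantile(shares, [0.05, 0.95])
            hits += lo <= 0.5 <= hi
        assert hits >= 4

    def test_non_centered_input_fatal(self):
        X, y = toy_problem(50, 3)
        with pytest.raises(ValueError, match="not centered"):
            gibbs_bayesc(X + 1.0, y)
        with pytest.raises(ValueError, match="y is not centered"):
            gibbs_bayesc(X, y + 5.0)

    def test_zero_variance_column_fatal(self):
        X, y = toy_problem(50, 3)
        X[:, 1] = 0.0
        with pytest.raises(ValueError, match="zero-variance"):
            gibbs_bayesc(X, y)


class TestDrawsAndSummary:
    def _fixture_draws(self):
        delta = np.array(
            [[1, 0, 1], [1, 0, 0], [1, 1, 0], [1, 0, 0], [1, 0, 1],
             [1, 0, 0], [1, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1]],
            dtype=np.int8,
        )
        rng = np.random.default_rng(0)
        beta = delta * rng.standard_normal(delta.shape)
        return beta, delta

    def test_pip_is_inclusion_frequency(self):
        beta, delta = self._fixture_draws()
        draws = PosteriorDraws.from_dense(
            beta, delta, np.full(10, 0.1), np.ones(10), np.ones(10)
        )
        summ = summarize(draws)
        np.testing.assert_allclose(summ.pip, [0.9, 0.2, 0.3])
        np.testing.assert_allclose(summ.lfdr, 1 - summ.pip)

    def test_sparse_reconstruction_exact(self):
        beta, delta = self._fixture_draws()
        draws = PosteriorDraws.from_dense(
            beta, delta, np.full(10, 0.1), np.ones(10), np.ones(10)
        )
        np.testing.assert_array_equal(draws.beta_matrix(), beta)
        np.testing.assert_array_equal(draws.delta_matrix(), delta.astype(bool))

    def test_post_mean_matches_dense_average(self):
        beta, delta = self._fixture_draws()
        draws = PosteriorDraws.from_dense(
            beta, delta, np.full(10, 0.1), np.ones(10), np.ones(10)
        )
        np.testing.assert_allclose(
            summarize(draws).post_mean_beta, beta.mean(axis=0), atol=1e-12
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)
        with pytest.raises(ValueError):
            BayesCPrior(alpha1=0.0)
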