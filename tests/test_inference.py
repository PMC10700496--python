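"""Convergence diagnostics, HDI, and the HMC fit contract."""

import numpy as np
import pytest

from bayes2pl import (
    ChainSpec,
    FixedItems2PL,
    GeneratingCondition,
    Hierarchical2PL,
    HyperpriorConfig,
    ResponseMatrix,
    check_convergence,
    gelman_rubin,
    generate_dataset,
    hdi,
)
from bayes2pl.mml import EMSettings, eap_scores
from bayes2pl.transforms import ItemParameterSet

FAST = ChainSpec(n_chains=3, n_iterations=700, n_burnin=300, seed=42, max_leapfrog=20)


def _rhat_oracle(chains):
    """Hand-coded between/within variance formula."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = np.mean([np.var(c, ddof=1) for c in chains])
    B = n * np.var(means, ddof=1)
    return np.sqrt(((n - 1) / n * W + B / n) / W)


class TestGelmanRubin:
    def test_constant_chains_give_exactly_one(self):
        assert gelman_rubin(np.full((2, 100), 3.7)) == 1.0

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 10_000))
        assert 0.99 <= gelman_rubin(x) <= 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert gelman_rubin(x) > 1.05
        assert gelman_rubin(x) == pytest.approx(_rhat_oracle(x), abs=1e-10)

    def test_matches_formula_oracle_on_fixed_chains(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, size=(3, 500))
        assert gelman_rubin(x) == pytest.approx(_rhat_oracle(x), abs=1e-10)

    def test_requires_two_chains_and_enough_draws(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((2, 5)))


class TestHDI:
    def test_brute_force_ten_points(self):
        samples = np.arange(1, 11, dtype=float)
        assert hdi(samples, 0.5) == (1.0, 5.0)  # ties broken to lowest start

    def test_matches_exhaustive_window_search(self, rng):
        x = np.sort(rng.lognormal(size=200))
        k = int(np.ceil(0.9 * x.size))
        widths = [x[i + k - 1] - x[i] for i in range(x.size - k + 1)]
        i = int(np.argmin(widths))
        assert hdi(x, 0.9) == (x[i], x[i + k - 1])

    def test_symmetric_sample_close_to_equal_tails(self, rng):
        x = rng.standard_normal(200_000)
        lo, hi = hdi(x, 0.95)
        qlo, qhi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(qlo, abs=0.05)
        assert hi == pytest.approx(qhi, abs=0.05)

    def test_degenerate_sample(self):
        assert hdi(np.full(50, 2.5), 0.95) == (2.5, 2.5)

    def test_never_wider_than_equal_tailed(self, rng):
        for _ in range(20):
            x = rng.gamma(rng.uniform(0.5, 5), size=500)
            lo, hi = hdi(x, 0.9)
            qlo, qhi = np.quantile(x, [0.05, 0.95])
            assert hi - lo <= qhi - qlo + 1e-12

    def test_mass_domain(self):
        with pytest.raises(ValueError):
            hdi(np.arange(10.0), 1.0)


class TestConvergenceFlag:
    def test_all_below_threshold(self):
        assert check_convergence({"a": 1.01, "b": 1.04}) is True

    def test_one_above(self):
        assert check_convergence({"a": 1.01, "b": 1.06}) is False

    def test_boundary_is_strict(self):
        assert check_convergence({"a": 1.05}) is False


class TestFitContract:
    def test_identical_seeds_give_identical_summaries(self, small_y):
        spec = ChainSpec(n_chains=2, n_iterations=220, n_burnin=100, seed=9)
        m = Hierarchical2PL(small_y, HyperpriorConfig.from_label("exponential", "WI2"))
        t1 = m.fit(spec).summary_table
        t2 = m.fit(spec).summary_table
        assert (t1 == t2).all().all()

    def test_perfect_item_still_yields_finite_estimates(self, rng):
        """An all-correct item needs no adjustment in the hierarchical model."""
        ds = generate_dataset(GeneratingCondition(50, 8, (0.25, 0.90), 0.3, seed=3))
        y = ds.responses.y.copy()
        y[:, 0] = 1  # perfect response pattern
        res = Hierarchical2PL(
            ResponseMatrix(y), HyperpriorConfig.from_label("exponential", "WI2")
        ).fit(FAST)
        assert np.all(np.isfinite(res.posterior_mean("alpha")))
        assert np.all(np.isfinite(res.posterior_mean("beta")))
        assert np.all(res.posterior_mean("alpha") > 0)

    def test_theta_posterior_mean_matches_eap_quadrature(self, small_dataset):
        """With items fixed, HMC posterior means of theta equal EAP scores
        computed by numerical integration, within Monte-Carlo error."""
        y = small_dataset.responses
        items = small_dataset.items
        res = FixedItems2PL(y, items.alpha, items.beta).fit(
            ChainSpec(n_chains=3, n_iterations=1400, n_burnin=400, seed=5))
        post_mean = res.posterior_mean("theta")
        eap = eap_scores(y, items=items, settings=EMSettings(n_quadrature=81)).theta
        t = res.summary_table
        n_beyond_3se = 0
        for j in range(y.n_persons):
            row = t.loc[f"theta[{j + 1}]"]
            se = row["sd"] / np.sqrt(max(row["ess"], 1.0))
            dev = abs(post_mean[j] - eap[j])
            # 60 simultaneous checks: tolerate a couple of 3-SE exceedances
            assert dev < max(5 * se, 0.05)
            n_beyond_3se += dev >= max(3 * se, 0.02)
        assert n_beyond_3se <= 2

    def test_item_recovery_correlates_with_truth(self):
        """At N=500 the posterior means track the generating items as well as
        a marginal-ML oracle fit to the same data (the correlation ceiling is
        set by the data, not the sampler)."""
        from bayes2pl import Marginal2PL

        ds = generate_dataset(GeneratingCondition(500, 25, (0.25, 0.90), 0.3, seed=21))
        res = Hierarchical2PL(
            ds.responses, HyperpriorConfig.from_label("exponential", "WI2")
        ).fit(ChainSpec(n_chains=3, n_iterations=600, n_burnin=250, seed=13,
                        max_leapfrog=20))
        oracle = Marginal2PL(ds.responses).fit()
        r_alpha = np.corrcoef(res.posterior_mean("alpha"), ds.items.alpha)[0, 1]
        r_beta = np.corrcoef(res.posterior_mean("beta"), ds.items.beta)[0, 1]
        r_alpha_oracle = np.corrcoef(oracle.alpha, ds.items.alpha)[0, 1]
        assert r_alpha > r_alpha_oracle - 0.05
        assert r_alpha > 0.8
        assert r_beta > 0.95

    def test_item_bias_small_at_large_n(self):
        """Item-averaged |bias| of alpha and beta stays below 0.1 at N=500,
        k=50 (typical variances) over 10 replications."""
        config = HyperpriorConfig.from_label("exponential", "WI2")
        dev_a, dev_b = [], []
        for rep in range(10):
            ds = generate_dataset(GeneratingCondition(500, 50, (0.25, 0.90), 0.3,
                                                      seed=100 + rep))
            res = Hierarchical2PL(ds.responses, config).fit(
                ChainSpec(n_chains=3, n_iterations=500, n_burnin=220,
                          seed=500 + rep, max_leapfrog=16))
            dev_a.append(float(np.mean(res.posterior_mean("alpha") - ds.items.alpha)))
            dev_b.append(float(np.mean(res.posterior_mean("beta") - ds.items.beta)))
        assert abs(np.mean(dev_a)) < 0.1
        assert abs(np.mean(dev_b)) < 0.1
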