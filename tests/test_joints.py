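"""Log-joint builders against independent term-by-term oracles."""

import numpy as np
import pytest
from scipy import stats

from bayes2pl import (
    HyperpriorConfig,
    ResponseMatrix,
    iw_h2pl_log_joint,
    nonhier_2pl_log_joint,
    oh2pl_log_joint,
)
from bayes2pl.joints import bernoulli_loglik, inv_wishart_logpdf
from bayes2pl.transforms import NonCenteredState, lkj_cholesky_2x2, noncentered_to_classical
from bayes2pl._targets import (
    FixedItemsTarget,
    IWH2PLTarget,
    Nonhier2PLTarget,
    OH2PLTarget,
)


def test_single_bernoulli_cell_is_log_half():
    y = ResponseMatrix(np.array([[1]]))
    assert bernoulli_loglik([1.0], [0.0], [0.0], y) == pytest.approx(np.log(0.5))


def test_missing_cells_contribute_nothing():
    y_full = ResponseMatrix(np.array([[1, 0], [0, 1]]))
    y_miss = ResponseMatrix(np.array([[1, 0], [0, 1]]),
                            mask=np.array([[True, True], [True, False]]))
    alpha, beta, theta = [1.2, 0.8], [0.3, -0.5], [0.4, -1.0]
    full = bernoulli_loglik(alpha, beta, theta, y_full)
    miss = bernoulli_loglik(alpha, beta, theta, y_miss)
    # removing the (1,1) cell removes exactly its Bernoulli term
    p = 1 / (1 + np.exp(-0.8 * (-1.0 + 0.5)))
    assert miss == pytest.approx(full - np.log(p), abs=1e-12)


def _toy_state(rho=0.25):
    xt = np.array([[0.4, -1.1], [0.9, 0.2]])
    return NonCenteredState(xi_tilde=xt, tau_alpha_unif=0.7, tau_beta_unif=0.4,
                            mu_alpha=0.1, mu_beta=-0.3,
                            L_omega=lkj_cholesky_2x2(rho),
                            theta=np.array([0.5, -0.8]))


@pytest.mark.parametrize("family,label", [("half_cauchy", "WI2"),
                                          ("exponential", "WI1"),
                                          ("inv_gamma", "WI1")])
def test_oh2pl_log_joint_term_by_term(toy_y, family, label):
    """Sum of independently computed scipy prior terms + likelihood."""
    config = HyperpriorConfig.from_label(family, label)
    state = _toy_state()
    items, hyper = noncentered_to_classical(state, config)

    expected = bernoulli_loglik(items.alpha, items.beta, state.theta, toy_y)
    expected += stats.norm.logpdf(state.theta).sum()
    expected += stats.norm.logpdf(state.xi_tilde).sum()
    expected += stats.norm.logpdf(state.mu_alpha, scale=1.0)
    expected += stats.norm.logpdf(state.mu_beta, scale=2.0)
    expected += 2 * np.log(state.L_omega[1, 1])  # LKJ(2), K=2
    if family == "half_cauchy":
        expected += 2 * stats.uniform(0, np.pi / 2).logpdf(state.tau_alpha_unif)
    elif family == "exponential":
        expected += 2 * stats.uniform(0, 1).logpdf(state.tau_alpha_unif)
    else:
        a, b = config.params["shape"], config.params["scale"]
        expected += stats.invgamma(a, scale=b).logpdf(hyper.tau_alpha)
        expected += stats.invgamma(a, scale=b).logpdf(hyper.tau_beta)

    assert oh2pl_log_joint(state, toy_y, config) == pytest.approx(expected, abs=1e-8)


def test_oh2pl_log_joint_unchanged_by_missing_cell():
    config = HyperpriorConfig.from_label("exponential", "WI2")
    state = _toy_state()
    y2 = ResponseMatrix(np.array([[1, 0], [0, 1]]),
                        mask=np.array([[True, True], [False, True]]))
    y1 = ResponseMatrix(np.array([[1, 0], [9, 1]]) % 2,
                        mask=np.array([[True, True], [False, True]]))
    assert oh2pl_log_joint(state, y2, config) == pytest.approx(
        oh2pl_log_joint(state, y1, config))


class TestInverseWishartJoint:
    def test_iw_density_matches_scipy(self):
        for Sigma in (np.eye(2), np.array([[1.3, 0.4], [0.4, 0.9]])):
            ours = inv_wishart_logpdf(Sigma, 3.0, np.eye(2))
            ref = stats.invwishart(df=3, scale=np.eye(2)).logpdf(Sigma)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_toy_term_by_term(self, toy_y):
        params = dict(theta=np.array([0.5, -0.8]),
                      xi=np.array([[0.2, -0.1], [0.6, -0.9]]),
                      mu=np.array([0.1, -0.3]),
                      Sigma=np.array([[0.3, 0.1], [0.1, 0.8]]))
        alpha = np.exp(params["xi"][0])
        expected = bernoulli_loglik(alpha, params["xi"][1], params["theta"], toy_y)
        expected += stats.norm.logpdf(params["theta"]).sum()
        expected += stats.multivariate_normal(params["mu"], params["Sigma"]).logpdf(
            params["xi"].T).sum()
        expected += stats.norm.logpdf(params["mu"][0], scale=1.0)
        expected += stats.norm.logpdf(params["mu"][1], scale=2.0)
        expected += stats.invwishart(df=3, scale=np.eye(2)).logpdf(params["Sigma"])
        assert iw_h2pl_log_joint(params, toy_y) == pytest.approx(expected, abs=1e-8)

    def test_likelihood_term_identical_to_oh2pl(self, toy_y):
        """Joint differences across two y matrices isolate the likelihood:
        priors cancel, so both models must agree on that difference."""
        y2 = ResponseMatrix(np.array([[0, 1], [1, 1]]))
        params = dict(theta=np.array([0.3, 0.9]),
                      xi=np.array([np.log([1.4, 0.7]), [0.2, -1.0]]),
                      mu=np.zeros(2), Sigma=np.eye(2))
        iw_diff = iw_h2pl_log_joint(params, toy_y) - iw_h2pl_log_joint(params, y2)
        ll_diff = (bernoulli_loglik([1.4, 0.7], [0.2, -1.0], params["theta"], toy_y)
                   - bernoulli_loglik([1.4, 0.7], [0.2, -1.0], params["theta"], y2))
        assert iw_diff == pytest.approx(ll_diff, abs=1e-10)

    def test_rejects_non_pd_sigma(self, toy_y):
        params = dict(theta=np.zeros(2), xi=np.zeros((2, 2)), mu=np.zeros(2),
                      Sigma=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            iw_h2pl_log_joint(params, toy_y)


class TestNonhierarchicalJoint:
    def test_lognormal_term_at_mode_argument(self, toy_y):
        # alpha = 1: logN(0,1) density is 1/sqrt(2 pi)
        params = dict(theta=np.zeros(2), alpha=np.ones(2), beta=np.zeros(2))
        lp = nonhier_2pl_log_joint(params, toy_y)
        expected = bernoulli_loglik(params["alpha"], params["beta"], params["theta"], toy_y)
        expected += stats.norm.logpdf(params["theta"]).sum()
        expected += 2 * stats.lognorm(s=1.0).logpdf(1.0)
        expected += 2 * stats.norm.logpdf(0.0, scale=2.0)
        assert lp == pytest.approx(expected, abs=1e-10)
        assert stats.lognorm(s=1.0).logpdf(1.0) == pytest.approx(-np.log(np.sqrt(2 * np.pi)))
        assert stats.norm.logpdf(0.0, scale=2.0) == pytest.approx(-np.log(2 * np.sqrt(2 * np.pi)))

    def test_toy_term_by_term(self, toy_y, rng):
        params = dict(theta=rng.normal(size=2), alpha=rng.uniform(0.5, 2, 2),
                      beta=rng.normal(size=2))
        expected = bernoulli_loglik(params["alpha"], params["beta"], params["theta"], toy_y)
        expected += stats.norm.logpdf(params["theta"]).sum()
        expected += stats.lognorm(s=1.0).logpdf(params["alpha"]).sum()
        expected += stats.norm.logpdf(params["beta"], scale=2.0).sum()
        assert nonhier_2pl_log_joint(params, toy_y) == pytest.approx(expected, abs=1e-10)

    def test_rejects_nonpositive_alpha(self, toy_y):
        with pytest.raises(ValueError):
            nonhier_2pl_log_joint(dict(theta=np.zeros(2), alpha=np.array([1.0, -0.2]),
                                       beta=np.zeros(2)), toy_y)


@pytest.mark.parametrize("make_target", [
    lambda y: OH2PLTarget(y, HyperpriorConfig.from_label("half_cauchy", "WI2")),
    lambda y: OH2PLTarget(y, HyperpriorConfig.from_label("exponential", "NI1")),
    lambda y: OH2PLTarget(y, HyperpriorConfig.from_label("inv_gamma", "WI1")),
    lambda y: IWH2PLTarget(y),
    lambda y: Nonhier2PLTarget(y),
    lambda y: FixedItemsTarget(y, np.array([1.0, 1.5]), np.array([0.0, -0.4])),
], ids=["oh2pl-hc", "oh2pl-exp", "oh2pl-ig", "iw", "nonhier", "fixed"])
def test_analytic_gradients_match_finite_differences(make_target, rng):
    """Every HMC target's gradient agrees with central differences."""
    y = ResponseMatrix((rng.uniform(size=(5, 2)) < 0.6).astype(int))
    target = make_target(y)
    v = rng.uniform(-0.9, 0.9, target.dim)
    _, g = target.logp_grad(v)
    eps = 1e-6
    for i in range(target.dim):
        vp, vm = v.copy(), v.copy()
        vp[i] += eps
        vm[i] -= eps
        fd = (target.logp(vp) - target.logp(vm)) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=5e-5, abs=5e-6)


def test_oh2pl_target_logp_matches_joint_plus_jacobian(toy_y):
    """Unconstrained target density = constrained joint + transform Jacobians."""
    config = HyperpriorConfig.from_label("exponential", "WI2")
    target = OH2PLTarget(toy_y, config)
    rng = np.random.default_rng(5)
    v = rng.uniform(-0.8, 0.8, target.dim)
    c = target.constrain(v)
    state = NonCenteredState(
        xi_tilde=np.vstack([c["z_alpha"], c["z_beta"]]),
        tau_alpha_unif=np.exp(-c["tau_alpha"] / config.tau_scale),
        tau_beta_unif=np.exp(-c["tau_beta"] / config.tau_scale),
        mu_alpha=c["mu_alpha"], mu_beta=c["mu_beta"],
        L_omega=lkj_cholesky_2x2(c["rho"]), theta=c["theta"])
    joint = oh2pl_log_joint(state, toy_y, config)

    def sig(x):
        return 1 / (1 + np.exp(-x))

    jac = 0.0
    for vx in v[-3:-1]:  # the two auxiliary coordinates
        jac += np.log(sig(vx)) + np.log(1 - sig(vx))
    jac += np.log(1 - c["rho"] ** 2)  # tanh coordinate
    assert target.logp(v) == pytest.approx(joint + jac, abs=1e-8)
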