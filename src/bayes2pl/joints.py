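"""Joint log-densities of the three Bayesian 2PL variants.

These builders evaluate the log joint (likelihood + priors) on the
constrained parameter scale.  They are the reference definitions of the
models; the HMC targets in :mod:`bayes2pl._targets` reproduce them on an
unconstrained scale (adding the change-of-variables Jacobians) with
analytic gradients.

Models
------
* optimized hierarchical 2PL (non-centered, separation strategy, bounded
  uniform auxiliaries for the scales);
* standard hierarchical 2PL with an inverse-Wishart(3, I) prior on the
  item-parameter covariance matrix (centered);
* nonhierarchical 2PL with independent logN(0,1) / N(0,2) item priors.

All normal priors written N(0, 2) are read with 2 as the standard
deviation (the Stan convention) unless a config requests the variance
reading.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .data import ResponseMatrix
from .families import HyperpriorConfig
from .link import log1pexp
from .transforms import (
    NonCenteredState,
    lkj_log_density,
    noncentered_to_classical,
)

__all__ = [
    "bernoulli_loglik",
    "oh2pl_log_joint",
    "iw_h2pl_log_joint",
    "nonhier_2pl_log_joint",
    "inv_gamma_logpdf",
    "inv_wishart_logpdf",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _norm_logpdf(x, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * (x / sd) ** 2


def inv_gamma_logpdf(x, shape, scale):
    """log density of the inverse-Gamma(shape a, scale b) at x > 0."""
    if x <= 0:
        return -np.inf
    a, b = shape, scale
    return a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x


def inv_wishart_logpdf(Sigma, df, Psi):
    """log density of the inverse-Wishart(df, Psi) at a p x p SPD matrix."""
    Sigma = np.asarray(Sigma, dtype=float)
    p = Sigma.shape[0]
    sign, logdet_S = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise ValueError("Sigma must be symmetric positive definite")
    _, logdet_P = np.linalg.slogdet(Psi)
    mvgamma = p * (p - 1) / 4.0 * np.log(np.pi) + sum(
        gammaln(df / 2.0 - i / 2.0) for i in range(p)
    )
    tr = np.trace(np.linalg.solve(Sigma, Psi))
    return (
        0.5 * df * logdet_P
        - 0.5 * df * p * np.log(2.0)
        - mvgamma
        - 0.5 * (df + p + 1.0) * logdet_S
        - 0.5 * tr
    )


def bernoulli_loglik(alpha, beta, theta, y: ResponseMatrix):
    """2PL Bernoulli log-likelihood over the observed cells of ``y``.

    Missing responses contribute zero.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if alpha.size != y.n_items or theta.size != y.n_persons:
        raise ValueError("parameter dimensions do not match the response matrix")
    eta = alpha[None, :] * (theta[:, None] - beta[None, :])
    # y*eta - log(1 + exp(eta)), overflow-safe
    terms = y.y * eta - log1pexp(eta)
    return float(np.sum(terms[y.mask]))


def oh2pl_log_joint(state: NonCenteredState, y: ResponseMatrix, config: HyperpriorConfig):
    """Log joint of the optimized (non-centered) hierarchical 2PL.

    Priors: theta ~ N(0,1); z-scores xi_tilde ~ N(0,1); mu_alpha ~ N(0,1);
    mu_beta ~ N(0,2); L_Omega ~ LKJ(eta) (unnormalized); bounded uniform
    auxiliaries for tau under the half-Cauchy / Exponential families, or an
    inverse-Gamma density on tau itself for the inverse-Gamma family.
    """
    if config.family not in ("half_cauchy", "exponential", "inv_gamma"):
        raise ValueError(f"family {config.family!r} does not define a non-centered model")
    items, hyper = noncentered_to_classical(state, config)
    lp = bernoulli_loglik(items.alpha, items.beta, state.theta, y)
    lp += float(np.sum(_norm_logpdf(state.theta, 1.0)))
    lp += float(np.sum(_norm_logpdf(state.xi_tilde, 1.0)))
    sd_b = np.sqrt(2.0) if config.scale_is_variance else 2.0
    lp += float(_norm_logpdf(state.mu_alpha, 1.0))
    lp += float(_norm_logpdf(state.mu_beta, sd_b))
    lp += lkj_log_density(state.L_omega, config.lkj_eta)
    if config.family == "half_cauchy":
        lp += 2.0 * -np.log(np.pi / 2.0)  # U(0, pi/2) density for both auxiliaries
    elif config.family == "exponential":
        lp += 0.0  # U(0, 1) density
    else:
        a, b = config.params["shape"], config.params["scale"]
        if config.ig_on_variance:
            # prior on tau^2, with the tau -> tau^2 change of variables
            lp += inv_gamma_logpdf(hyper.tau_alpha**2, a, b) + np.log(2 * hyper.tau_alpha)
            lp += inv_gamma_logpdf(hyper.tau_beta**2, a, b) + np.log(2 * hyper.tau_beta)
        else:
            lp += inv_gamma_logpdf(hyper.tau_alpha, a, b)
            lp += inv_gamma_logpdf(hyper.tau_beta, a, b)
    return lp


def iw_h2pl_log_joint(params: dict, y: ResponseMatrix, df: float = 3.0,
                      scale_is_variance: bool = False):
    """Log joint of the standard (centered) inverse-Wishart hierarchical 2PL.

    ``params`` holds ``theta`` (N,), ``xi`` (2 x I with rows log-alpha and
    beta), ``mu`` (2,) and ``Sigma`` (2x2 SPD).  Priors:
    theta ~ N(0,1); xi_i ~ MVN(mu, Sigma); mu_alpha ~ N(0,1);
    mu_beta ~ N(0,2); Sigma ~ IW(df, I).
    """
    theta = np.asarray(params["theta"], dtype=float)
    xi = np.asarray(params["xi"], dtype=float)
    mu = np.asarray(params["mu"], dtype=float)
    Sigma = np.asarray(params["Sigma"], dtype=float)
    alpha = np.exp(xi[0])
    beta = xi[1]
    lp = bernoulli_loglik(alpha, beta, theta, y)
    lp += float(np.sum(_norm_logpdf(theta, 1.0)))
    # MVN prior on each item's (log alpha, beta)
    L = np.linalg.cholesky(Sigma)
    z = np.linalg.solve(L, xi - mu[:, None])
    I = xi.shape[1]
    lp += float(-I * _LOG_2PI - I * np.sum(np.log(np.diag(L))) - 0.5 * np.sum(z**2))
    sd_b = np.sqrt(2.0) if scale_is_variance else 2.0
    lp += float(_norm_logpdf(mu[0], 1.0) + _norm_logpdf(mu[1], sd_b))
    lp += float(inv_wishart_logpdf(Sigma, df, np.eye(2)))
    return lp


def nonhier_2pl_log_joint(params: dict, y: ResponseMatrix,
                          scale_is_variance: bool = False):
    """Log joint of the nonhierarchical 2PL.

    ``params`` holds ``theta`` (N,), ``alpha`` (I,) > 0 and ``beta`` (I,).
    Priors: theta ~ N(0,1); alpha ~ logN(0,1); beta ~ N(0,2).
    """
    theta = np.asarray(params["theta"], dtype=float)
    alpha = np.asarray(params["alpha"], dtype=float)
    beta = np.asarray(params["beta"], dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("discriminations must be strictly positive")
    lp = bernoulli_loglik(alpha, beta, theta, y)
    lp += float(np.sum(_norm_logpdf(theta, 1.0)))
    # lognormal(0, 1) on alpha
    la = np.log(alpha)
    lp += float(np.sum(-la - 0.5 * _LOG_2PI - 0.5 * la**2))
    sd_b = np.sqrt(2.0) if scale_is_variance else 2.0
    lp += float(np.sum(_norm_logpdf(beta, sd_b)))
    return lp
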