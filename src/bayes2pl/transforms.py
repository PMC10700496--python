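"""Non-centered parameterization of the hierarchical 2PL.

The optimized hierarchical 2PL samples uncorrelated z-scores and bounded
auxiliary variables and transforms them deterministically to the classical
item parameters:

* ``xi_i = (Lambda @ L_Omega @ xi_tilde_i)`` with ``Lambda = diag(tau_alpha,
  tau_beta)`` and ``L_Omega`` the Cholesky factor of the item-parameter
  correlation matrix (the "separation strategy": separate priors for scales
  and correlation);
* ``alpha_i = exp(mu_alpha + xi_alpha_i)``, ``beta_i = mu_beta + xi_beta_i``;
* the scales come from bounded uniform auxiliaries:
  ``tau = s * tan(u)`` with ``u ~ U(0, pi/2)`` implies tau ~ half-Cauchy(0, s),
  ``tau = s * (-log u)`` with ``u ~ U(0, 1)`` implies tau ~ Exponential(mean s).

This removes the funnel-shaped cross-level dependencies between the item
parameters and their hyperparameters from the posterior geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .families import HyperpriorConfig

__all__ = [
    "ItemParameterSet",
    "LatentAbilities",
    "HyperParameters",
    "NonCenteredState",
    "half_cauchy_from_uniform",
    "exponential_from_uniform",
    "lkj_log_density",
    "lkj_cholesky_2x2",
    "noncentered_to_classical",
    "classical_to_noncentered",
]


@dataclass
class ItemParameterSet:
    """Classical 2PL item parameters: discriminations and difficulties."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have the same length")
        if not (np.all(np.isfinite(self.alpha)) and np.all(np.isfinite(self.beta))):
            raise ValueError("item parameters must be finite")
        if np.any(self.alpha <= 0):
            raise ValueError("discriminations must be strictly positive")

    def __len__(self):
        return self.alpha.size


@dataclass
class LatentAbilities:
    """Person abilities theta on the logit scale."""

    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("abilities must be finite")

    def __len__(self):
        return self.theta.size


@dataclass
class HyperParameters:
    """Grand means, scales and correlation Cholesky of the item parameters.

    ``L_omega @ L_omega.T`` is the 2x2 correlation matrix of
    (log alpha, beta); ``tau_alpha``/``tau_beta`` are the corresponding
    scale (standard deviation) components.
    """

    mu_alpha: float
    mu_beta: float
    tau_alpha: float
    tau_beta: float
    L_omega: np.ndarray

    def __post_init__(self):
        if not (self.tau_alpha > 0 and self.tau_beta > 0):
            raise ValueError("scale components tau must be > 0")
        L = np.asarray(self.L_omega, dtype=float)
        if L.shape != (2, 2) or L[0, 1] != 0.0:
            raise ValueError("L_omega must be 2x2 lower triangular")
        if np.any(np.diag(L) <= 0):
            raise ValueError("L_omega diagonal must be positive")
        if not np.allclose(np.sum(L**2, axis=1), 1.0, atol=1e-8):
            raise ValueError("L_omega rows must have unit norm (correlation Cholesky)")
        self.L_omega = L

    @property
    def correlation(self) -> float:
        """Implied correlation between log-discrimination and difficulty."""
        return float(self.L_omega[1, 0])

    @property
    def Lambda(self) -> np.ndarray:
        return np.diag([self.tau_alpha, self.tau_beta])


@dataclass
class NonCenteredState:
    """Actively sampled state of the non-centered hierarchical 2PL.

    ``xi_tilde`` is the 2 x I matrix of z-scores (row 0: log-discrimination
    dimension, row 1: difficulty dimension).  ``tau_alpha_unif`` and
    ``tau_beta_unif`` live in (0, pi/2) for the half-Cauchy family and in
    (0, 1) for the Exponential family; for the inverse-Gamma family they
    hold the scales tau directly (on (0, inf)).
    """

    xi_tilde: np.ndarray
    tau_alpha_unif: float
    tau_beta_unif: float
    mu_alpha: float
    mu_beta: float
    L_omega: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.xi_tilde = np.asarray(self.xi_tilde, dtype=float)
        if self.xi_tilde.ndim != 2 or self.xi_tilde.shape[0] != 2:
            raise ValueError("xi_tilde must be a 2 x I matrix")
        if not np.all(np.isfinite(self.xi_tilde)):
            raise ValueError("xi_tilde must be finite")
        self.L_omega = np.asarray(self.L_omega, dtype=float)
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))


def half_cauchy_from_uniform(u, scale):
    """Map ``u in (0, pi/2)`` to ``scale * tan(u)``.

    If ``u ~ Uniform(0, pi/2)`` the result follows a half-Cauchy(0, scale)
    distribution; the map is strictly increasing.  ``u`` is clipped one
    machine epsilon inside the open interval before taking the tangent.
    """
    u = np.asarray(u, dtype=float)
    if not scale > 0:
        raise ValueError("scale must be > 0")
    if np.any(u <= 0) or np.any(u >= np.pi / 2):
        raise ValueError("u must lie strictly inside (0, pi/2)")
    eps = np.finfo(float).eps
    u = np.clip(u, eps, np.pi / 2 - eps)
    out = scale * np.tan(u)
    return out if out.ndim else float(out)


def exponential_from_uniform(u, scale):
    """Map ``u in (0, 1)`` to ``scale * (-log u)``.

    If ``u ~ Uniform(0, 1)`` the result is Exponential with mean ``scale``
    (rate ``1/scale``).
    """
    u = np.asarray(u, dtype=float)
    if not scale > 0:
        raise ValueError("scale must be > 0")
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    out = scale * (-np.log(u))
    return out if out.ndim else float(out)


def lkj_log_density(L_omega, eta):
    """Unnormalized log LKJ density of a correlation Cholesky factor.

    ``log p(L | eta) = sum_{k=2}^{K} (K - k + 2*eta - 2) * log L_kk``.
    For eta = 2 the density mildly favors matrices near the identity
    (small correlations).
    """
    if not eta > 0:
        raise ValueError("LKJ shape eta must be > 0")
    L = np.asarray(L_omega, dtype=float)
    K = L.shape[0]
    diag = np.diag(L)
    if np.any(diag <= 0):
        raise ValueError("Cholesky diagonal must be positive")
    k = np.arange(2, K + 1)
    return float(np.sum((K - k + 2.0 * eta - 2.0) * np.log(diag[1:])))


def lkj_cholesky_2x2(rho):
    """Correlation Cholesky factor [[1, 0], [rho, sqrt(1-rho^2)]]."""
    if not -1.0 < rho < 1.0:
        raise ValueError("correlation must lie in (-1, 1)")
    return np.array([[1.0, 0.0], [rho, np.sqrt(1.0 - rho * rho)]])


def _taus_from_state(state: NonCenteredState, config: HyperpriorConfig):
    if config.family == "half_cauchy":
        s = config.tau_scale
        return (
            half_cauchy_from_uniform(state.tau_alpha_unif, s),
            half_cauchy_from_uniform(state.tau_beta_unif, s),
        )
    if config.family == "exponential":
        s = config.tau_scale
        return (
            exponential_from_uniform(state.tau_alpha_unif, s),
            exponential_from_uniform(state.tau_beta_unif, s),
        )
    if config.family == "inv_gamma":
        # no auxiliary trick: the state carries tau directly
        if state.tau_alpha_unif <= 0 or state.tau_beta_unif <= 0:
            raise ValueError("tau must be > 0 for the inverse-Gamma family")
        return float(state.tau_alpha_unif), float(state.tau_beta_unif)
    raise ValueError(f"family {config.family!r} is not a non-centered hierarchical family")


def noncentered_to_classical(state: NonCenteredState, config: HyperpriorConfig):
    """Transform a non-centered state to classical item parameters.

    Returns ``(ItemParameterSet, HyperParameters)``.  Deterministic and,
    for fixed hyperparameters, bijective in the z-scores.
    """
    tau_a, tau_b = _taus_from_state(state, config)
    L = np.asarray(state.L_omega, dtype=float)
    Lam = np.diag([tau_a, tau_b])
    xi = Lam @ L @ state.xi_tilde  # 2 x I
    alpha = np.exp(state.mu_alpha + xi[0])
    beta = state.mu_beta + xi[1]
    items = ItemParameterSet(alpha=alpha, beta=beta)
    hyper = HyperParameters(
        mu_alpha=float(state.mu_alpha),
        mu_beta=float(state.mu_beta),
        tau_alpha=tau_a,
        tau_beta=tau_b,
        L_omega=L,
    )
    return items, hyper


def classical_to_noncentered(
    items: ItemParameterSet,
    hyper: HyperParameters,
    config: HyperpriorConfig | None = None,
    theta=None,
):
    """Invert :func:`noncentered_to_classical` for given hyperparameters.

    Recovers the z-scores ``xi_tilde = (Lambda L_Omega)^{-1} xi`` from the
    classical item parameters, and the bounded auxiliaries by inverting the
    family transform (``u = arctan(tau/s)`` for half-Cauchy,
    ``u = exp(-tau/s)`` for Exponential); without a config, or for the
    inverse-Gamma family, the auxiliary slots carry tau directly.
    """
    xi = np.vstack([np.log(items.alpha) - hyper.mu_alpha, items.beta - hyper.mu_beta])
    A = hyper.Lambda @ hyper.L_omega
    xi_tilde = np.linalg.solve(A, xi)
    ua, ub = hyper.tau_alpha, hyper.tau_beta
    if config is not None and config.family == "half_cauchy":
        s = config.tau_scale
        ua, ub = np.arctan(ua / s), np.arctan(ub / s)
    elif config is not None and config.family == "exponential":
        s = config.tau_scale
        ua, ub = np.exp(-ua / s), np.exp(-ub / s)
    return NonCenteredState(
        xi_tilde=xi_tilde,
        tau_alpha_unif=float(ua),
        tau_beta_unif=float(ub),
        mu_alpha=hyper.mu_alpha,
        mu_beta=hyper.mu_beta,
        L_omega=hyper.L_omega,
        theta=np.zeros(0) if theta is None else theta,
    )
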