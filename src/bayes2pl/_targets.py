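"""Unconstrained posterior targets with analytic gradients for HMC.

Each target maps an unconstrained parameter vector ``v`` to the log
posterior density (the corresponding :mod:`bayes2pl.joints` log joint plus
change-of-variables Jacobians) and its gradient.  Transforms used:

* bounded uniform auxiliaries via scaled sigmoids,
* positive scales via exp,
* the correlation (2x2 Cholesky) via tanh,
* covariance matrices via a log-diagonal Cholesky factor.

Gradients are exact (verified against finite differences in the test
suite), which keeps leapfrog integration cheap: one gradient evaluation is
O(N * I).
"""

from __future__ import annotations

import numpy as np

from .data import ResponseMatrix
from .families import HyperpriorConfig

_LOG_2PI = np.log(2.0 * np.pi)


_TINY = 1e-300


def _sigmoid(x):
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    # keep strictly inside (0, 1): a saturated auxiliary would otherwise
    # produce log(0) noise before the proposal is rejected
    return np.clip(s, 1e-16, float(np.nextafter(1.0, 0.0)))


def _loglik_grads(alpha, beta, theta, y, mask):
    """2PL Bernoulli log-likelihood and its gradients.

    Returns (ll, d/dtheta (N,), d/dalpha (I,), d/dbeta (I,)).

    Non-finite intermediate values (possible on extreme leapfrog
    excursions) yield a non-finite log-density and a rejected proposal;
    the numpy warnings for those transients are suppressed.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        return _loglik_grads_inner(alpha, beta, theta, y, mask)


def _loglik_grads_inner(alpha, beta, theta, y, mask):
    eta = alpha[None, :] * (theta[:, None] - beta[None, :])
    # p and log1pexp, overflow-safe
    ae = np.abs(eta)
    softplus = np.where(eta > 0, eta, 0.0) + np.log1p(np.exp(-ae))
    p = np.where(eta >= 0, 1.0 / (1.0 + np.exp(-ae)), np.exp(-ae) / (1.0 + np.exp(-ae)))
    ll = float(np.sum((y * eta - softplus)[mask]))
    g = np.where(mask, y - p, 0.0)  # N x I
    d_theta = g @ alpha
    d_alpha = np.sum(g * (theta[:, None] - beta[None, :]), axis=0)
    d_beta = -alpha * np.sum(g, axis=0)
    return ll, d_theta, d_alpha, d_beta


class BaseTarget:
    """Shared plumbing: dimension bookkeeping and response data."""

    def __init__(self, y: ResponseMatrix):
        self.y_mat = np.asarray(y.y, dtype=float)
        self.mask = np.asarray(y.mask, dtype=bool)
        self.N, self.I = self.y_mat.shape

    def logp(self, v):
        return self.logp_grad(v)[0]

    def initial(self, rng, jitter=1.0):
        """Dispersed random start: uniform(-1, 1) on the unconstrained scale."""
        return jitter * rng.uniform(-1.0, 1.0, self.dim)


class OH2PLTarget(BaseTarget):
    """Optimized hierarchical 2PL, non-centered, one hyperprior config.

    Layout of ``v``: theta (N) | z_alpha (I) | z_beta (I) | mu_alpha |
    mu_beta | v_tau_alpha | v_tau_beta | v_rho.
    """

    def __init__(self, y: ResponseMatrix, config: HyperpriorConfig):
        super().__init__(y)
        if config.family not in ("half_cauchy", "exponential", "inv_gamma"):
            raise ValueError(f"family {config.family!r} not supported by the non-centered model")
        self.config = config
        self.dim = self.N + 2 * self.I + 5
        self.sd_b = np.sqrt(2.0) if config.scale_is_variance else 2.0

    def _split(self, v):
        N, I = self.N, self.I
        theta = v[:N]
        za = v[N:N + I]
        zb = v[N + I:N + 2 * I]
        mu_a, mu_b, va, vb, vr = v[N + 2 * I:]
        return theta, za, zb, mu_a, mu_b, va, vb, vr

    def _tau(self, vx):
        """Constrained tau, d tau/dv, and the Jacobian term with its grad."""
        cfg = self.config
        if cfg.family == "half_cauchy":
            s = cfg.tau_scale
            sig = float(_sigmoid(vx))
            u = (np.pi / 2.0) * sig
            tau = s * np.tan(u)
            dtau = (s + tau * tau / s) * (np.pi / 2.0) * sig * (1.0 - sig)
            logj = np.log(np.pi / 2.0) + np.log(sig) + np.log1p(-sig)
            dlogj = 1.0 - 2.0 * sig
            logprior = -np.log(np.pi / 2.0)  # U(0, pi/2) on the auxiliary
            dlogprior_dtau = 0.0
        elif cfg.family == "exponential":
            s = cfg.tau_scale
            sig = float(_sigmoid(vx))
            tau = -s * np.log(sig)
            dtau = -s * (1.0 - sig)
            logj = np.log(sig) + np.log1p(-sig)
            dlogj = 1.0 - 2.0 * sig
            logprior = 0.0  # U(0, 1) on the auxiliary
            dlogprior_dtau = 0.0
        else:  # inv_gamma: tau sampled directly on (0, inf) via exp
            a, b = cfg.params["shape"], cfg.params["scale"]
            tau = float(np.exp(vx))
            dtau = tau
            logj = float(vx)
            dlogj = 1.0
            if cfg.ig_on_variance:
                from .joints import inv_gamma_logpdf
                logprior = inv_gamma_logpdf(tau * tau, a, b) + np.log(2.0 * tau)
                dlogprior_dtau = (-(a + 1.0) / (tau * tau) + b / tau**4) * 2.0 * tau + 1.0 / tau
            else:
                from .joints import inv_gamma_logpdf
                logprior = inv_gamma_logpdf(tau, a, b)
                dlogprior_dtau = -(a + 1.0) / tau + b / (tau * tau)
        return tau, dtau, logj, dlogj, logprior, dlogprior_dtau

    def constrain(self, v):
        """Constrained-scale parameters for one unconstrained vector."""
        theta, za, zb, mu_a, mu_b, va, vb, vr = self._split(v)
        tau_a = self._tau(va)[0]
        tau_b = self._tau(vb)[0]
        r = np.tanh(vr)
        w = np.sqrt(1.0 - r * r)
        xi_a = tau_a * za
        xi_b = tau_b * (r * za + w * zb)
        alpha = np.exp(mu_a + xi_a)
        beta = mu_b + xi_b
        return dict(theta=theta, alpha=alpha, beta=beta, mu_alpha=mu_a, mu_beta=mu_b,
                    tau_alpha=tau_a, tau_beta=tau_b, rho=r,
                    z_alpha=za, z_beta=zb)

    def logp_grad(self, v):
        with np.errstate(over="ignore", invalid="ignore"):
            return self._logp_grad_inner(v)

    def _logp_grad_inner(self, v):
        theta, za, zb, mu_a, mu_b, va, vb, vr = self._split(v)
        eta_lkj = self.config.lkj_eta
        tau_a, dtau_a, logj_a, dlogj_a, lpr_a, dlpr_a = self._tau(va)
        tau_b, dtau_b, logj_b, dlogj_b, lpr_b, dlpr_b = self._tau(vb)
        r = np.tanh(vr)
        w = np.sqrt(max(1.0 - r * r, 1e-300))

        xi_a = tau_a * za
        xi_b = tau_b * (r * za + w * zb)
        alpha = np.exp(mu_a + xi_a)
        beta = mu_b + xi_b

        ll, d_theta, d_alpha, d_beta = _loglik_grads(alpha, beta, theta, self.y_mat, self.mask)

        lp = ll
        # priors on theta, z-scores, grand means
        lp += -0.5 * float(theta @ theta) - 0.5 * self.N * _LOG_2PI
        lp += -0.5 * float(za @ za + zb @ zb) - self.I * _LOG_2PI
        lp += -0.5 * _LOG_2PI - 0.5 * mu_a * mu_a
        lp += -0.5 * _LOG_2PI - np.log(self.sd_b) - 0.5 * (mu_b / self.sd_b) ** 2
        # LKJ(eta) on the correlation Cholesky: (2 eta - 2) * log L22
        lp += (eta_lkj - 1.0) * np.log(max(1.0 - r * r, _TINY))
        # tau priors and unconstraining Jacobians
        lp += lpr_a + lpr_b + logj_a + logj_b
        # tanh Jacobian for rho
        lp += np.log(max(1.0 - r * r, _TINY))

        # chain rule back to the unconstrained coordinates
        d_xi_a = d_alpha * alpha  # dL/d xi_a through alpha = exp(mu_a + xi_a)
        d_xi_b = d_beta

        g = np.empty_like(v)
        g[:self.N] = d_theta - theta
        g[self.N:self.N + self.I] = d_xi_a * tau_a + d_xi_b * tau_b * r - za
        g[self.N + self.I:self.N + 2 * self.I] = d_xi_b * tau_b * w - zb
        d_mu_a = float(np.sum(d_alpha * alpha)) - mu_a
        d_mu_b = float(np.sum(d_beta)) - mu_b / self.sd_b**2
        d_tau_a_tot = float(np.sum(d_xi_a * za)) + dlpr_a
        d_tau_b_tot = float(np.sum(d_xi_b * (r * za + w * zb))) + dlpr_b
        d_va = d_tau_a_tot * dtau_a + dlogj_a
        d_vb = d_tau_b_tot * dtau_b + dlogj_b
        d_r = float(np.sum(d_xi_b * tau_b * (za - zb * r / w)))
        d_vr = d_r * (1.0 - r * r) + (eta_lkj - 1.0) * (-2.0 * r) + (-2.0 * r)
        g[self.N + 2 * self.I:] = (d_mu_a, d_mu_b, d_va, d_vb, d_vr)
        return lp, g

    def unpack_draws(self, V):
        """Classical-scale parameter arrays for a (draws, dim) matrix."""
        n = V.shape[0]
        out = dict(theta=np.empty((n, self.N)), alpha=np.empty((n, self.I)),
                   beta=np.empty((n, self.I)), mu_alpha=np.empty(n), mu_beta=np.empty(n),
                   tau_alpha=np.empty(n), tau_beta=np.empty(n), rho=np.empty(n))
        for d in range(n):
            c = self.constrain(V[d])
            for k in out:
                out[k][d] = c[k]
        return out


class IWH2PLTarget(BaseTarget):
    """Centered hierarchical 2PL with an inverse-Wishart(df, I) prior.

    Layout of ``v``: theta (N) | xi_alpha (I, = log alpha) | xi_beta (I) |
    mu_alpha | mu_beta | l11 | l21 | l22, where Sigma = L L^T with
    L = [[exp(l11), 0], [l21, exp(l22)]].
    """

    def __init__(self, y: ResponseMatrix, df: float = 3.0, scale_is_variance: bool = False):
        super().__init__(y)
        self.df = float(df)
        self.dim = self.N + 2 * self.I + 5
        self.sd_b = np.sqrt(2.0) if scale_is_variance else 2.0

    def _split(self, v):
        N, I = self.N, self.I
        return (v[:N], v[N:N + I], v[N + I:N + 2 * I],
                v[N + 2 * I], v[N + 2 * I + 1],
                v[N + 2 * I + 2], v[N + 2 * I + 3], v[N + 2 * I + 4])

    def constrain(self, v):
        theta, xa, xb, mu_a, mu_b, l11, l21, l22 = self._split(v)
        L11, L21, L22 = np.exp(l11), l21, np.exp(l22)
        Sigma = np.array([[L11 * L11, L11 * L21], [L11 * L21, L21 * L21 + L22 * L22]])
        tau_a, tau_b = np.sqrt(Sigma[0, 0]), np.sqrt(Sigma[1, 1])
        return dict(theta=theta, alpha=np.exp(xa), beta=xb, mu_alpha=mu_a, mu_beta=mu_b,
                    Sigma=Sigma, tau_alpha=tau_a, tau_beta=tau_b,
                    rho=Sigma[0, 1] / (tau_a * tau_b), xi=np.vstack([xa, xb]))

    def logp_grad(self, v):
        with np.errstate(over="ignore", invalid="ignore"):
            return self._logp_grad_inner(v)

    def _logp_grad_inner(self, v):
        theta, xa, xb, mu_a, mu_b, l11, l21, l22 = self._split(v)
        L11, L21, L22 = np.exp(l11), l21, np.exp(l22)
        nu, I = self.df, self.I
        alpha = np.exp(xa)
        beta = xb
        ll, d_theta, d_alpha, d_beta = _loglik_grads(alpha, beta, theta, self.y_mat, self.mask)

        d1 = xa - mu_a
        d2 = xb - mu_b
        z1 = d1 / L11
        z2 = (d2 - L21 * z1) / L22

        lp = ll
        lp += -0.5 * float(theta @ theta) - 0.5 * self.N * _LOG_2PI
        # MVN(mu, Sigma) on the item vectors
        lp += -I * _LOG_2PI - I * (np.log(L11) + np.log(L22)) - 0.5 * float(z1 @ z1 + z2 @ z2)
        lp += -0.5 * _LOG_2PI - 0.5 * mu_a * mu_a
        lp += -0.5 * _LOG_2PI - np.log(self.sd_b) - 0.5 * (mu_b / self.sd_b) ** 2
        # IW(nu, identity): -((nu+3)/2) log|Sigma| - 0.5 tr(Sigma^-1) + const
        from scipy.special import gammaln
        const = -nu * np.log(2.0) - (0.5 * np.log(np.pi) + gammaln(nu / 2.0) + gammaln(nu / 2.0 - 0.5))
        logdet = 2.0 * (np.log(L11) + np.log(L22))
        trinv = 1.0 / L11**2 + L21**2 / (L11**2 * L22**2) + 1.0 / L22**2
        lp += const - 0.5 * (nu + 3.0) * logdet - 0.5 * trinv
        # Jacobian of (l11, l21, l22) -> Sigma
        lp += np.log(4.0) + 3.0 * np.log(L11) + 2.0 * np.log(L22)

        # gradients
        g = np.empty_like(v)
        g[:self.N] = d_theta - theta
        # prior gradient w.r.t. the item vectors
        dQ_d1 = -z1 / L11 + z2 * L21 / (L11 * L22)
        dQ_d2 = -z2 / L22
        g[self.N:self.N + I] = d_alpha * alpha + dQ_d1
        g[self.N + I:self.N + 2 * I] = d_beta + dQ_d2
        g[self.N + 2 * I] = -float(np.sum(dQ_d1)) - mu_a
        g[self.N + 2 * I + 1] = -float(np.sum(dQ_d2)) - mu_b / self.sd_b**2

        # scalar derivatives w.r.t. the Cholesky entries
        dL11 = float(np.sum(z1 * z1 / L11 - z2 * z1 * L21 / (L11 * L22))) - I / L11
        dL21 = float(np.sum(z2 * z1 / L22))
        dL22 = float(np.sum(z2 * z2 / L22)) - I / L22
        # IW prior terms
        dL11 += -(nu + 3.0) / L11 + (1.0 / L11**3 + L21**2 / (L11**3 * L22**2))
        dL21 += -L21 / (L11**2 * L22**2)
        dL22 += -(nu + 3.0) / L22 + (L21**2 / (L11**2 * L22**3) + 1.0 / L22**3)
        # chain to unconstrained (exp on the diagonal) + Jacobian gradients
        g[self.N + 2 * I + 2] = dL11 * L11 + 3.0
        g[self.N + 2 * I + 3] = dL21
        g[self.N + 2 * I + 4] = dL22 * L22 + 2.0
        return lp, g

    def unpack_draws(self, V):
        n = V.shape[0]
        out = dict(theta=np.empty((n, self.N)), alpha=np.empty((n, self.I)),
                   beta=np.empty((n, self.I)), mu_alpha=np.empty(n), mu_beta=np.empty(n),
                   tau_alpha=np.empty(n), tau_beta=np.empty(n), rho=np.empty(n))
        for d in range(n):
            c = self.constrain(V[d])
            for k in out:
                out[k][d] = c[k]
        return out


class Nonhier2PLTarget(BaseTarget):
    """Nonhierarchical 2PL: theta ~ N(0,1), alpha ~ logN(0,1), beta ~ N(0,2).

    Layout of ``v``: theta (N) | log alpha (I) | beta (I).  Sampling
    log alpha with a N(0,1) prior is exactly the logN(0,1) prior on alpha
    after the change of variables.
    """

    def __init__(self, y: ResponseMatrix, scale_is_variance: bool = False):
        super().__init__(y)
        self.dim = self.N + 2 * self.I
        self.sd_b = np.sqrt(2.0) if scale_is_variance else 2.0

    def constrain(self, v):
        N, I = self.N, self.I
        return dict(theta=v[:N], alpha=np.exp(v[N:N + I]), beta=v[N + I:N + 2 * I])

    def logp_grad(self, v):
        with np.errstate(over="ignore", invalid="ignore"):
            return self._logp_grad_inner(v)

    def _logp_grad_inner(self, v):
        N, I = self.N, self.I
        theta = v[:N]
        la = v[N:N + I]
        beta = v[N + I:]
        alpha = np.exp(la)
        ll, d_theta, d_alpha, d_beta = _loglik_grads(alpha, beta, theta, self.y_mat, self.mask)
        lp = ll
        lp += -0.5 * float(theta @ theta) - 0.5 * N * _LOG_2PI
        lp += -0.5 * float(la @ la) - 0.5 * I * _LOG_2PI
        lp += float(np.sum(-0.5 * (beta / self.sd_b) ** 2)) - I * (0.5 * _LOG_2PI + np.log(self.sd_b))
        g = np.empty_like(v)
        g[:N] = d_theta - theta
        g[N:N + I] = d_alpha * alpha - la
        g[N + I:] = d_beta - beta / self.sd_b**2
        return lp, g

    def unpack_draws(self, V):
        n = V.shape[0]
        N, I = self.N, self.I
        return dict(theta=V[:, :N].copy(), alpha=np.exp(V[:, N:N + I]),
                    beta=V[:, N + I:].copy())


class FixedItemsTarget(BaseTarget):
    """Ability-only posterior with known item parameters (theta ~ N(0,1))."""

    def __init__(self, y: ResponseMatrix, alpha, beta):
        super().__init__(y)
        self.alpha = np.asarray(alpha, dtype=float)
        self.beta = np.asarray(beta, dtype=float)
        self.dim = self.N

    def constrain(self, v):
        return dict(theta=v)

    def logp_grad(self, v):
        ll, d_theta, _, _ = _loglik_grads(self.alpha, self.beta, v, self.y_mat, self.mask)
        lp = ll - 0.5 * float(v @ v) - 0.5 * self.N * _LOG_2PI
        return lp, d_theta - v

    def unpack_draws(self, V):
        return dict(theta=V.copy())
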