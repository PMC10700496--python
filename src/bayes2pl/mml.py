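"""Marginal maximum likelihood estimation of the 2PL (Bock–Aitkin EM).

The ability distribution theta ~ N(0,1) is integrated out on a fixed
quadrature grid.  The E-step computes each person's posterior weights on
the grid and the expected correct/attempt counts per item; the M-step
maximizes a weighted Bernoulli logistic likelihood per item in the
slope/intercept parameterization ``P = logistic(a*theta + c)`` by Newton's
method.  The marginal log-likelihood is non-decreasing across iterations.

Estimates are transformed to the classical parameterization
(alpha = a, beta = -c/a) and screened for inadmissibility: non-convergence,
non-positive discriminations, or estimates beyond configurable caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data import ResponseMatrix
from .transforms import ItemParameterSet, LatentAbilities

__all__ = [
    "EMSettings",
    "SlopeInterceptParams",
    "MMLResult",
    "Marginal2PL",
    "fit_mml",
    "slope_intercept_to_classical",
    "screen_admissible",
    "eap_scores",
]


@dataclass(frozen=True)
class EMSettings:
    """EM control: quadrature size/range, iteration cap, LL tolerance."""

    n_quadrature: int = 41
    grid_range: tuple = (-6.0, 6.0)
    max_iterations: int = 500
    tolerance: float = 1e-6
    gauss_hermite: bool = False
    alpha_cap: float = 10.0
    beta_cap: float = 10.0
    #: optional per-item lognormal(mu, sd) penalty on the slope, keyed by
    #: item index — the "rescue prior" for boundary response patterns
    slope_penalty: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_quadrature < 11:
            raise ValueError("need at least 11 quadrature points")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class SlopeInterceptParams:
    """Slope/intercept item parameters of ``logistic(a*theta + c)``."""

    a: np.ndarray
    c: np.ndarray


@dataclass
class MMLResult:
    """Outcome of one marginal-ML fit."""

    slope_intercept: SlopeInterceptParams
    items: ItemParameterSet | None
    eap: LatentAbilities
    converged: bool
    admissible: bool
    loglik_trace: np.ndarray
    boundary_items: np.ndarray  # all-0 or all-1 response patterns

    @property
    def alpha(self):
        return self.slope_intercept.a

    @property
    def beta(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.slope_intercept.a != 0,
                            -self.slope_intercept.c / self.slope_intercept.a, np.nan)


def quadrature_grid(settings: EMSettings):
    """Grid nodes and N(0,1) weights (normalized)."""
    if settings.gauss_hermite:
        nodes, w = np.polynomial.hermite_e.hermegauss(settings.n_quadrature)
        weights = w / w.sum()
        return nodes, weights
    nodes = np.linspace(*settings.grid_range, settings.n_quadrature)
    w = norm.pdf(nodes)
    return nodes, w / w.sum()


def slope_intercept_to_classical(params: SlopeInterceptParams):
    """alpha = a, beta = -c/a; items with a <= 0 are flagged, not raised.

    Returns (ItemParameterSet or None, per-item admissible mask).  The
    ItemParameterSet is None when any item is inadmissible (alpha <= 0 is
    not representable in the classical container).
    """
    a = np.asarray(params.a, dtype=float)
    c = np.asarray(params.c, dtype=float)
    ok = (a > 0) & np.isfinite(a) & np.isfinite(c)
    if not ok.all():
        return None, ok
    return ItemParameterSet(alpha=a, beta=-c / a), ok


def _item_newton(nodes, r, n, a, c, penalty=None, n_steps=50, tol=1e-9):
    """Maximize sum_q [r*eta - n*log(1+e^eta)], eta = a*nodes + c."""
    for _ in range(n_steps):
        eta = a * nodes + c
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1.0 - p)
        ga = float(np.sum((r - n * p) * nodes))
        gc = float(np.sum(r - n * p))
        haa = float(np.sum(w * nodes * nodes))
        hac = float(np.sum(w * nodes))
        hcc = float(np.sum(w))
        if penalty is not None and a > 0:
            mu, sd = penalty
            la = np.log(a)
            ga += (-(la - mu) / sd**2 - 1.0) / a
            # negative second derivative of the penalty (observed information)
            haa += max((1.0 / sd**2 - (la - mu) / sd**2 - 1.0) / a**2, 0.0)
        det = haa * hcc - hac * hac
        if det <= 1e-12:
            break
        da = (gc * hac - ga * hcc) / det * -1.0
        dc = (ga * hac - gc * haa) / det * -1.0
        # damped step to keep eta in a sane range
        step = 1.0
        while step > 1e-4 and (abs(da * step) > 5 or abs(dc * step) > 5):
            step *= 0.5
        a += step * da
        c += step * dc
        if abs(da) < tol and abs(dc) < tol:
            break
    return a, c


class Marginal2PL:
    """Marginal-ML (Bock–Aitkin EM) model for a response matrix."""

    def __init__(self, y, settings: EMSettings | None = None):
        if not isinstance(y, ResponseMatrix):
            y = ResponseMatrix(np.asarray(y))
        self.y = y
        self.settings = settings or EMSettings()

    def fit(self) -> MMLResult:
        st = self.settings
        y, mask = self.y.y.astype(float), self.y.mask
        N, I = y.shape
        nodes, prior_w = quadrature_grid(st)
        Q = nodes.size

        observed = mask.astype(float)
        prop = np.where(mask, y, 0.0).sum(axis=0) / observed.sum(axis=0)
        boundary = (prop == 0.0) | (prop == 1.0)

        # moment-style starting values
        a = np.ones(I)
        c = np.log(np.clip(prop, 0.02, 0.98) / (1 - np.clip(prop, 0.02, 0.98)))

        trace = []
        converged = False
        for _ in range(st.max_iterations):
            eta = np.outer(nodes, a) + c  # Q x I
            logp1 = -np.log1p(np.exp(-np.abs(eta))) - np.where(eta < 0, -eta, 0.0)
            logp0 = logp1 - eta
            # person x grid log joint: sum over observed items
            ll_grid = (np.where(mask, y, 0.0) @ logp1.T
                       + np.where(mask, 1 - y, 0.0) @ logp0.T)  # N x Q
            ll_grid += np.log(prior_w)[None, :]
            mx = ll_grid.max(axis=1, keepdims=True)
            lik = np.exp(ll_grid - mx)
            marg = lik.sum(axis=1)
            loglik = float(np.sum(np.log(marg) + mx.ravel()))
            trace.append(loglik)
            w = lik / marg[:, None]  # posterior weights, N x Q

            # expected counts per item and node
            r = (np.where(mask, y, 0.0)).T @ w  # I x Q
            n_exp = observed.T @ w  # I x Q

            for i in range(I):
                pen = st.slope_penalty.get(i)
                a[i], c[i] = _item_newton(nodes, r[i], n_exp[i], a[i], c[i], penalty=pen)

            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < st.tolerance:
                converged = True
                break

        slope = SlopeInterceptParams(a=a.copy(), c=c.copy())
        items, ok = slope_intercept_to_classical(slope)
        eap = eap_scores(self.y, slope_intercept=slope, settings=st)
        result = MMLResult(
            slope_intercept=slope, items=items, eap=eap, converged=converged,
            admissible=True, loglik_trace=np.asarray(trace), boundary_items=boundary,
        )
        result.admissible = screen_admissible(result, alpha_cap=st.alpha_cap,
                                              beta_cap=st.beta_cap)
        return result


def fit_mml(y, settings: EMSettings | None = None) -> MMLResult:
    """Functional entry point over :class:`Marginal2PL`."""
    return Marginal2PL(y, settings=settings).fit()


def screen_admissible(result: MMLResult, alpha_cap: float = 10.0,
                      beta_cap: float = 10.0) -> bool:
    """Admissibility screen for a marginal-ML fit.

    False when the EM did not converge, any discrimination is <= 0 or
    non-finite, or any estimate exceeds the caps (|alpha| > alpha_cap,
    |beta| > beta_cap).
    """
    if not result.converged:
        return False
    a = result.alpha
    b = result.beta
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        return False
    if np.any(a > alpha_cap):
        return False
    if np.any(~np.isfinite(b)) or np.any(np.abs(b) > beta_cap):
        return False
    return True


def eap_scores(y, items: ItemParameterSet | None = None,
               slope_intercept: SlopeInterceptParams | None = None,
               settings: EMSettings | None = None) -> LatentAbilities:
    """Expected-a-posteriori abilities on the quadrature grid.

    Posterior mean of theta per person under the N(0,1) population prior,
    given fixed item parameters (classical or slope/intercept form).
    """
    if not isinstance(y, ResponseMatrix):
        y = ResponseMatrix(np.asarray(y))
    st = settings or EMSettings()
    nodes, prior_w = quadrature_grid(st)
    if slope_intercept is None:
        if items is None:
            raise ValueError("provide item parameters")
        a = items.alpha
        c = -items.alpha * items.beta
    else:
        a, c = slope_intercept.a, slope_intercept.c
    eta = np.outer(nodes, a) + c
    logp1 = -np.log1p(np.exp(-np.abs(eta))) - np.where(eta < 0, -eta, 0.0)
    logp0 = logp1 - eta
    yv, mask = y.y.astype(float), y.mask
    ll_grid = (np.where(mask, yv, 0.0) @ logp1.T
               + np.where(mask, 1 - yv, 0.0) @ logp0.T)
    ll_grid += np.log(prior_w)[None, :]
    mx = ll_grid.max(axis=1, keepdims=True)
    w = np.exp(ll_grid - mx)
    w /= w.sum(axis=1, keepdims=True)
    return LatentAbilities(theta=w @ nodes)
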