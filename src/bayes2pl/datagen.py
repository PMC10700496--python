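"""Synthetic data generation for 2PL parameter-recovery studies.

Item parameters are produced by a three-step procedure on the natural
(alpha, beta) scale:

1. draw (alpha, beta) pairs from a bivariate normal with grand mean (1, 0)
   truncated to the box [0.65, 4.0] x [-4.5, 4.5] (rejection sampling);
2. rescale the sample to the *exact* target covariance
   Sigma = tau_diag @ Omega @ tau_diag (center, whiten with the inverse
   Cholesky factor of the sample covariance, color with the Cholesky factor
   of Sigma) — sample SDs and correlation then match the targets to
   floating-point precision, for every seed;
3. shift each column so its sample mean equals the true marginal mean of
   the truncated bivariate normal (computed by numerical integration).

Abilities are standard normal; responses are independent Bernoulli draws
from the 2PL response probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .data import ResponseMatrix
from .link import response_probability
from .transforms import ItemParameterSet, LatentAbilities

__all__ = [
    "TruncationBox",
    "GeneratingCondition",
    "GeneratedDataset",
    "STUDY_TAU_PAIRS",
    "draw_truncated_bvn",
    "exact_covariance_rescale",
    "truncated_bvn_means",
    "recentre_to_truncated_means",
    "generate_item_parameters",
    "generate_abilities",
    "generate_responses",
    "generate_dataset",
]

#: the three scale pairs of the study design: small, typical, extreme
STUDY_TAU_PAIRS = ((0.10, 0.40), (0.25, 0.90), (0.75, 1.50))


@dataclass(frozen=True)
class TruncationBox:
    """Axis-aligned truncation region with the generating grand mean."""

    grand_mean: tuple = (1.0, 0.0)
    lower: tuple = (0.65, -4.5)
    upper: tuple = (4.0, 4.5)

    def __post_init__(self):
        lo, hi, mu = map(np.asarray, (self.lower, self.upper, self.grand_mean))
        if not np.all(lo < hi):
            raise ValueError("lower limits must be below upper limits")
        if not np.all((lo < mu) & (mu < hi)):
            raise ValueError("grand mean must lie inside the box")


@dataclass(frozen=True)
class GeneratingCondition:
    """One data-generating cell: sizes, scale pair, correlation, seed."""

    n_persons: int
    n_items: int
    tau_pair: tuple = (0.25, 0.90)
    rho: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [-1, 1]")
        if not all(t > 0 for t in self.tau_pair):
            raise ValueError("scale components must be > 0")

    @property
    def Sigma(self) -> np.ndarray:
        """Target covariance tau_diag @ Omega @ tau_diag."""
        ta, tb = self.tau_pair
        return np.array([[ta * ta, self.rho * ta * tb],
                         [self.rho * ta * tb, tb * tb]])


@dataclass
class GeneratedDataset:
    """Responses plus the generating truth for one replication."""

    responses: ResponseMatrix
    items: ItemParameterSet
    abilities: LatentAbilities
    condition: GeneratingCondition
    Sigma: np.ndarray = field(default=None)


def draw_truncated_bvn(n, box: TruncationBox, cov, rng, max_batches=10000):
    """Rejection-sample n points of BVN(grand_mean, cov) inside the box.

    Raises when the acceptance rate falls below 1e-4 (infeasible
    box/covariance combination).
    """
    cov = np.asarray(cov, dtype=float)
    L = np.linalg.cholesky(cov)  # raises for non-PD input
    mu = np.asarray(box.grand_mean, dtype=float)
    lo = np.asarray(box.lower, dtype=float)
    hi = np.asarray(box.upper, dtype=float)
    out = np.empty((n, 2))
    filled = 0
    proposed = 0
    batch = max(4 * n, 256)
    for _ in range(max_batches):
        z = rng.standard_normal((batch, 2))
        x = mu + z @ L.T
        keep = np.all((x > lo) & (x < hi), axis=1)
        acc = x[keep]
        take = min(acc.shape[0], n - filled)
        out[filled:filled + take] = acc[:take]
        filled += take
        proposed += batch
        if filled == n:
            return out
        if proposed >= 1e4 and filled / proposed < 1e-4:
            break
    raise RuntimeError("truncated-normal acceptance rate below 1e-4; "
                       "box and covariance are incompatible")


def exact_covariance_rescale(Z, target_Sigma):
    """Linearly map an n x 2 sample to have *exact* sample covariance.

    Columns are centered, whitened with the inverse Cholesky factor of the
    sample covariance (n-1 denominator), and colored with the Cholesky
    factor of ``target_Sigma``; the output is centered with sample
    covariance equal to the target to ~1e-10.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 3:
        raise ValueError("need an n x d sample with n >= 3")
    target_Sigma = np.asarray(target_Sigma, dtype=float)
    C = Z - Z.mean(axis=0)
    S = C.T @ C / (Z.shape[0] - 1)
    if np.linalg.matrix_rank(S) < S.shape[0]:
        raise ValueError("sample covariance is singular")
    L_S = np.linalg.cholesky(S)
    L_T = np.linalg.cholesky(target_Sigma)
    white = np.linalg.solve(L_S, C.T)  # d x n, unit sample covariance
    return (L_T @ white).T


_MEANS_CACHE: dict = {}


def _trunc_moment_1d(mu1, s1, mu2, s2, rho, lo1, hi1, lo2, hi2, which, tol):
    """1-D reduction of a truncated-BVN moment over the first coordinate.

    Integrates the marginal density of x1 times the closed-form conditional
    contribution of x2 in [lo2, hi2]; ``which`` selects the integrand
    (0: mass, 1: E x1, 2: E x2).
    """
    from scipy.stats import norm

    s_cond = s2 * np.sqrt(max(1.0 - rho * rho, 1e-12))

    def f(x1):
        m_cond = mu2 + rho * s2 / s1 * (x1 - mu1)
        a = (lo2 - m_cond) / s_cond
        b = (hi2 - m_cond) / s_cond
        pz = norm.cdf(b) - norm.cdf(a)
        dens1 = norm.pdf((x1 - mu1) / s1) / s1
        if which == 0:
            return dens1 * pz
        if which == 1:
            return x1 * dens1 * pz
        # partial expectation of the conditional normal on [lo2, hi2]
        ex2 = m_cond * pz - s_cond * (norm.pdf(b) - norm.pdf(a))
        return dens1 * ex2

    val, err = integrate.quad(f, lo1, hi1, epsabs=tol, epsrel=tol, limit=200)
    if not np.isfinite(val):
        raise RuntimeError("numerical integration of truncated-normal moments failed")
    return val


def truncated_bvn_means(box: TruncationBox, cov, tol=1e-8):
    """Marginal means of BVN(grand_mean, cov) truncated to the box.

    Computed numerically (absolute tolerance ``tol``); infinite limits are
    supported.  Results are cached per (box, covariance) pair.
    """
    cov = np.asarray(cov, dtype=float)
    mu = np.asarray(box.grand_mean, dtype=float)
    lo = np.asarray(box.lower, dtype=float)
    hi = np.asarray(box.upper, dtype=float)
    key = (tuple(mu), tuple(lo), tuple(hi), tuple(np.round(cov.ravel(), 14)), tol)
    if key in _MEANS_CACHE:
        return _MEANS_CACHE[key].copy()
    s1, s2 = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
    rho = cov[0, 1] / (s1 * s2)
    mass = _trunc_moment_1d(mu[0], s1, mu[1], s2, rho, lo[0], hi[0], lo[1], hi[1], 0, tol)
    if mass <= 0:
        raise RuntimeError("truncation box has no probability mass")
    m1 = _trunc_moment_1d(mu[0], s1, mu[1], s2, rho, lo[0], hi[0], lo[1], hi[1], 1, tol)
    m2 = _trunc_moment_1d(mu[0], s1, mu[1], s2, rho, lo[0], hi[0], lo[1], hi[1], 2, tol)
    means = np.array([m1 / mass, m2 / mass])
    _MEANS_CACHE[key] = means
    return means.copy()


def recentre_to_truncated_means(X, box: TruncationBox, base_cov, means=None):
    """Shift each column to the truncated-normal marginal means.

    A pure per-column shift; ``means`` may be supplied to avoid recomputing
    the numerical integrals.
    """
    X = np.asarray(X, dtype=float)
    if means is None:
        means = truncated_bvn_means(box, base_cov)
    return X - X.mean(axis=0) + np.asarray(means, dtype=float)


def generate_item_parameters(cond: GeneratingCondition, rng,
                             box: TruncationBox | None = None,
                             enforce_range=True, max_redraws=100,
                             alpha_range=(0.5, 3.5), beta_range=(-4.0, 4.0),
                             log_scale=False):
    """Generate item parameters with exact sample moments.

    Composes truncated-BVN draws, exact covariance rescaling and
    recentring to the truncated means.  With ``enforce_range`` the whole
    item set is redrawn (up to ``max_redraws`` times) until all
    discriminations fall in ``alpha_range`` and difficulties in
    ``beta_range``.  With ``log_scale`` the first coordinate is treated as
    log alpha instead of alpha.

    Returns ``(ItemParameterSet, Sigma)``.  Requires at least 3 items (the
    sample covariance of fewer points is singular).
    """
    if cond.n_items < 3:
        raise ValueError("need at least 3 items for the exact-covariance rescaling")
    box = box or TruncationBox()
    Sigma = cond.Sigma
    means = truncated_bvn_means(box, Sigma)
    for _ in range(max_redraws + 1):
        Z = draw_truncated_bvn(cond.n_items, box, Sigma, rng)
        X = exact_covariance_rescale(Z, Sigma)
        X = recentre_to_truncated_means(X, box, Sigma, means=means)
        alpha = np.exp(X[:, 0]) if log_scale else X[:, 0]
        beta = X[:, 1]
        if not enforce_range:
            break
        ok = (np.all((alpha > alpha_range[0]) & (alpha < alpha_range[1]))
              and np.all((beta > beta_range[0]) & (beta < beta_range[1])))
        if ok:
            break
    else:
        raise RuntimeError(
            f"no item set inside alpha {alpha_range} / beta {beta_range} "
            f"after {max_redraws} redraws")
    if np.any(alpha <= 0):
        raise RuntimeError("generated non-positive discriminations; "
                           "use enforce_range or the log-scale generator")
    return ItemParameterSet(alpha=alpha, beta=beta), Sigma


def generate_abilities(n, rng) -> LatentAbilities:
    """iid standard-normal person abilities."""
    if n < 1:
        raise ValueError("need at least one person")
    return LatentAbilities(theta=rng.standard_normal(n))


def generate_responses(abilities: LatentAbilities, items: ItemParameterSet,
                       rng) -> ResponseMatrix:
    """Independent Bernoulli responses from the 2PL probabilities."""
    p = response_probability(abilities.theta[:, None], items.alpha[None, :],
                             items.beta[None, :])
    y = (rng.uniform(size=p.shape) < p).astype(np.int8)
    return ResponseMatrix(y=y)


def generate_dataset(cond: GeneratingCondition, rng=None,
                     box: TruncationBox | None = None,
                     enforce_range=True) -> GeneratedDataset:
    """One full replication: item parameters, abilities and responses."""
    if rng is None:
        rng = np.random.default_rng(cond.seed)
    items, Sigma = generate_item_parameters(cond, rng, box=box,
                                            enforce_range=enforce_range)
    abilities = generate_abilities(cond.n_persons, rng)
    responses = generate_responses(abilities, items, rng)
    return GeneratedDataset(responses=responses, items=items,
                            abilities=abilities, condition=cond, Sigma=Sigma)
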