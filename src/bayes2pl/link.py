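"""Item response function of the two-parameter logistic (2PL) model.

The 2PL models the probability that person ``j`` answers item ``i``
correctly as ``P(y_ij = 1) = logistic(alpha_i * (theta_j - beta_i))``,
where ``alpha_i > 0`` is the item discrimination, ``beta_i`` the item
difficulty and ``theta_j`` the person ability, all on the logit scale.
"""

from __future__ import annotations

import numpy as np

__all__ = ["irt_logit", "inverse_logit", "response_probability", "log1pexp"]


def log1pexp(x):
    """Overflow-safe ``log(1 + exp(x))`` (the softplus function)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    return out


def irt_logit(x):
    """Logistic (inverse-logit) function ``exp(x) / (1 + exp(x))``.

    Computed overflow-safely; returns values in the open interval (0, 1)
    for finite input.

    Parameters
    ----------
    x : float or ndarray
        Finite logit-scale argument.

    Raises
    ------
    ValueError
        If any entry of ``x`` is non-finite.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("irt_logit requires finite input")
    # exp(-|x|) never overflows; the two branches are algebraically equal
    e = np.exp(-np.abs(x))
    p = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    return p if p.ndim else float(p)


# common alias used throughout the package
inverse_logit = irt_logit


def response_probability(theta, alpha, beta):
    """2PL probability of a correct response, ``logistic(alpha*(theta-beta))``.

    Parameters
    ----------
    theta : float or ndarray
        Person ability.
    alpha : float or ndarray
        Item discrimination, strictly positive.
    beta : float or ndarray
        Item difficulty.

    Raises
    ------
    ValueError
        If any ``alpha`` is not strictly positive.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("item discrimination alpha must be > 0")
    return irt_logit(alpha * (np.asarray(theta, dtype=float) - np.asarray(beta, dtype=float)))
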