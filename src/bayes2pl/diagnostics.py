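"""Convergence diagnostics and posterior interval summaries."""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "hdi", "effective_sample_size", "check_convergence"]


def gelman_rubin(chains, split: bool = False):
    """Classic Gelman–Rubin potential scale reduction factor R-hat.

    Parameters
    ----------
    chains : array-like, shape (m, n)
        Draws of one scalar parameter from m >= 2 chains of equal length
        n >= 10.
    split : bool
        If True, each chain is split in half first (2m half-chains), the
        more conservative modern variant.  Default is the classic
        between/within statistic without rank normalization.

    Returns
    -------
    float
        R-hat; exactly 1.0 when every chain is constant.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with at least 2 chains")
    if x.shape[1] < 10:
        raise ValueError("need at least 10 draws per chain")
    if split:
        half = x.shape[1] // 2
        x = np.vstack([x[:, :half], x[:, half:2 * half]])
    m, n = x.shape
    chain_means = x.mean(axis=1)
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    if W == 0.0:
        return 1.0  # constant chains
    B = n * float(np.var(chain_means, ddof=1))
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def hdi(samples, mass: float = 0.95):
    """Shortest (highest-density) interval containing ``mass`` of a sample.

    Sample-based shortest contiguous window over the sorted draws; ties in
    width are broken toward the smaller lower bound.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 + np.arange(n - k + 1)] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest-start) minimum
    return float(x[i]), float(x[i + k - 1])


def effective_sample_size(chains):
    """Effective sample size from FFT autocorrelations.

    Pools the chain autocorrelation functions, truncates them with Geyer's
    initial positive sequence rule, and returns
    ``m * n / (1 + 2 * sum(rho_t))``.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 4:
        return float(m * n)
    acov = np.zeros(n)
    for c in range(m):
        d = x[c] - x[c].mean()
        size = 2 ** int(np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(d, size)
        ac = np.fft.irfft(f * np.conj(f), size)[:n].real / n
        acov += ac
    acov /= m
    if acov[0] <= 0:
        return float(m * n)
    rho = acov / acov[0]
    # Geyer initial positive sequence on paired sums
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(m * n / max(tau, 1.0))


def check_convergence(rhats, threshold: float = 1.05) -> bool:
    """True iff every monitored R-hat is strictly below ``threshold``."""
    vals = np.asarray([v for v in (rhats.values() if isinstance(rhats, dict) else rhats)],
                      dtype=float)
    return bool(np.all(vals < threshold))
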