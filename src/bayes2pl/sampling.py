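"""Gradient-based MCMC engine and the chain protocol.

A compact Hamiltonian Monte Carlo sampler: leapfrog integration with a
jittered number of steps, dual-averaging step-size adaptation towards a
target acceptance rate, and diagonal mass-matrix adaptation from the
first half of the burn-in window.  Any target object exposing ``dim``,
``logp_grad(v) -> (logp, grad)`` and ``initial(rng)`` can be sampled, so
the engine is pluggable.

The default chain protocol is three chains of 4000 iterations each with
1000 burn-in cycles and dispersed random starting values per chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChainSpec", "run_chains", "hmc_chain"]


@dataclass(frozen=True)
class ChainSpec:
    """MCMC chain protocol.

    Parameters
    ----------
    n_chains : int
        Number of independent chains (>= 2 for convergence diagnostics).
    n_iterations : int
        Total iterations per chain, including burn-in.
    n_burnin : int
        Burn-in (adaptation) iterations discarded from each chain.
    seed : int
        Master seed; each chain receives an independent child stream.
    max_leapfrog : int
        Upper bound of the jittered leapfrog trajectory length.
    target_accept : float
        Dual-averaging target acceptance probability.
    init_jitter : float
        Width of the dispersed uniform starting values.
    """

    n_chains: int = 3
    n_iterations: int = 4000
    n_burnin: int = 1000
    seed: int = 0
    max_leapfrog: int = 24
    target_accept: float = 0.8
    init_jitter: float = 1.0

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains")
        if not 0 < self.n_burnin < self.n_iterations:
            raise ValueError("need 0 < n_burnin < n_iterations")

    @property
    def n_kept(self) -> int:
        return self.n_iterations - self.n_burnin


def _leapfrog(v, p, eps, n_steps, grad, inv_mass):
    # overflow on a divergent trajectory yields a non-finite energy and a
    # rejected proposal; silence the transient numpy warnings
    with np.errstate(over="ignore", invalid="ignore"):
        return _leapfrog_inner(v, p, eps, n_steps, grad, inv_mass)


def _leapfrog_inner(v, p, eps, n_steps, grad, inv_mass):
    lp, g = grad(v)
    for _ in range(n_steps):
        p = p + 0.5 * eps * g
        v = v + eps * inv_mass * p
        lp, g = grad(v)
        if not np.isfinite(lp):
            return v, p, lp, g
        p = p + 0.5 * eps * g
    return v, p, lp, g


def hmc_chain(target, n_iterations, n_burnin, rng, max_leapfrog=24,
              target_accept=0.8, init=None, init_jitter=1.0):
    """Run one adaptive HMC chain; returns (draws, diagnostics dict).

    ``draws`` has shape (n_iterations - n_burnin, dim), burn-in excluded.
    Step size is tuned by Nesterov dual averaging during burn-in; a
    diagonal mass matrix is estimated from the draws of the first
    adaptation window and fixed afterwards.  Non-finite proposals count as
    divergences and are rejected.
    """
    dim = target.dim
    v = target.initial(rng, jitter=init_jitter) if init is None else np.array(init, dtype=float)
    lp, g = target.logp_grad(v)
    tries = 0
    while not np.isfinite(lp) and tries < 3:
        v = target.initial(rng, jitter=init_jitter)
        lp, g = target.logp_grad(v)
        tries += 1
    if not np.isfinite(lp):
        raise FloatingPointError("could not find a finite starting point after retries")

    inv_mass = np.ones(dim)
    sqrt_mass = np.ones(dim)

    # dual averaging state
    eps = 0.1
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    window_end = max(n_burnin // 2, 1)
    window = np.empty((window_end, dim))
    draws = np.empty((n_iterations - n_burnin, dim))
    n_accept = 0
    n_divergent = 0

    for it in range(n_iterations):
        p0 = rng.standard_normal(dim) * sqrt_mass
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        v_new, p_new, lp_new, _ = _leapfrog(v, p0, eps, n_steps, target.logp_grad, inv_mass)
        with np.errstate(over="ignore", invalid="ignore"):
            h0 = -lp + 0.5 * float(p0 * inv_mass @ p0)
            h1 = (-lp_new + 0.5 * float(p_new * inv_mass @ p_new)
                  if np.isfinite(lp_new) else np.inf)
            delta = h0 - h1
        if not np.isfinite(delta):
            accept_prob, accepted = 0.0, False
            n_divergent += 1
        else:
            accept_prob = min(1.0, np.exp(min(delta, 0.0)))
            accepted = np.log(rng.uniform()) < delta
        if accepted:
            v, lp = v_new, lp_new
            n_accept += 1

        if it < n_burnin:
            # dual averaging update
            m = it + 1
            h_bar = (1.0 - 1.0 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu_da - np.sqrt(m) / gamma * h_bar
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it < window_end:
                window[it] = v
            if it == window_end - 1 and window_end >= 10:
                var = np.var(window[window_end // 2:], axis=0)
                var = np.where(var > 1e-10, var, 1.0)
                inv_mass = var
                sqrt_mass = 1.0 / np.sqrt(var)
                # restart step-size adaptation under the new metric
                mu_da = np.log(10.0 * eps)
                h_bar, log_eps_bar = 0.0, 0.0
            if it == n_burnin - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_burnin] = v

    diag = dict(accept_rate=n_accept / n_iterations, step_size=eps,
                n_divergent=n_divergent)
    return draws, diag


def run_chains(target, chains: ChainSpec):
    """Run ``chains.n_chains`` independent HMC chains on ``target``.

    Returns (draws array of shape (n_chains, n_kept, dim), list of
    per-chain diagnostics).  Chains are seeded from independent child
    streams of ``chains.seed``, so results are reproducible bit-for-bit.
    """
    seeds = np.random.SeedSequence(chains.seed).spawn(chains.n_chains)
    all_draws = np.empty((chains.n_chains, chains.n_kept, target.dim))
    diags = []
    for c in range(chains.n_chains):
        rng = np.random.Generator(np.random.PCG64(seeds[c]))
        draws, diag = hmc_chain(
            target, chains.n_iterations, chains.n_burnin, rng,
            max_leapfrog=chains.max_leapfrog, target_accept=chains.target_accept,
            init_jitter=chains.init_jitter,
        )
        all_draws[c] = draws
        diags.append(diag)
    return all_draws, diags
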