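"""Posterior draws, summaries and fit results for the Bayesian 2PL models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import effective_sample_size, gelman_rubin, hdi

__all__ = ["PosteriorDraws", "BayesResults"]

#: hyperparameters monitored for the convergence flag (item calibration is
#: the target, so individual abilities are not monitored by default)
DEFAULT_MONITORED = ("alpha", "beta", "mu_alpha", "mu_beta", "tau_alpha", "tau_beta")


@dataclass
class PosteriorDraws:
    """Per-parameter posterior draw arrays indexed (chain, draw[, index]).

    Burn-in is already excluded; all chains hold the same number of draws.
    """

    params: dict = field(default_factory=dict)

    def __getitem__(self, name):
        return self.params[name]

    def __contains__(self, name):
        return name in self.params

    @property
    def n_chains(self):
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self):
        return next(iter(self.params.values())).shape[1]

    def scalar_series(self):
        """Yield (label, (chains, draws) array) for every scalar component."""
        for name, arr in self.params.items():
            if arr.ndim == 2:
                yield name, arr
            else:
                for i in range(arr.shape[2]):
                    yield f"{name}[{i + 1}]", arr[:, :, i]

    def pooled(self, name):
        """All chains concatenated, shape (chains*draws, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])


class BayesResults:
    """Posterior summaries of a fitted Bayesian 2PL model.

    Attributes
    ----------
    model_tag : str
        ``oh2pl``, ``iw_h2pl`` or ``nonhier_2pl``.
    draws : PosteriorDraws
        Classical-scale posterior draws (alpha, beta, theta, hyperparameters).
    converged : bool
        True iff every monitored R-hat < ``rhat_threshold``.
    """

    def __init__(self, model_tag, draws: PosteriorDraws, config=None,
                 monitored=DEFAULT_MONITORED, rhat_threshold=1.05,
                 point_estimate="mean", hdi_mass=0.95, sampler_diagnostics=None):
        self.model_tag = model_tag
        self.draws = draws
        self.config = config
        self.monitored = tuple(p for p in monitored if p in draws)
        self.rhat_threshold = rhat_threshold
        self.point_estimate = point_estimate
        self.hdi_mass = hdi_mass
        self.sampler_diagnostics = sampler_diagnostics or []
        self._table = None

    @property
    def summary_table(self) -> pd.DataFrame:
        if self._table is None:
            rows = []
            for label, arr in self.draws.scalar_series():
                pooled = arr.ravel()
                point = float(np.median(pooled)) if self.point_estimate == "median" else float(pooled.mean())
                lo, hi = hdi(pooled, self.hdi_mass)
                rows.append(dict(
                    parameter=label, mean=point, sd=float(pooled.std(ddof=1)),
                    hdi_low=lo, hdi_high=hi,
                    rhat=gelman_rubin(arr), ess=effective_sample_size(arr),
                ))
            self._table = pd.DataFrame(rows).set_index("parameter")
        return self._table

    @property
    def rhats(self) -> dict:
        t = self.summary_table
        return {p: float(t.loc[p, "rhat"]) for p in t.index}

    def monitored_rhats(self) -> dict:
        t = self.summary_table
        out = {}
        for name in self.monitored:
            for p in t.index:
                if p == name or p.startswith(f"{name}["):
                    out[p] = float(t.loc[p, "rhat"])
        return out

    @property
    def converged(self) -> bool:
        vals = np.array(list(self.monitored_rhats().values()))
        return bool(np.all(vals < self.rhat_threshold))

    def posterior_mean(self, name):
        """Posterior mean on the classical scale (chains pooled)."""
        return self.draws.pooled(name).mean(axis=0)

    @property
    def items(self):
        from .transforms import ItemParameterSet
        return ItemParameterSet(self.posterior_mean("alpha"), self.posterior_mean("beta"))

    @property
    def abilities(self):
        from .transforms import LatentAbilities
        return LatentAbilities(self.posterior_mean("theta"))

    def summary(self) -> str:
        t = self.summary_table
        head = (
            f"model: {self.model_tag}"
            + (f" ({self.config.family}/{self.config.label})" if getattr(self.config, "family", None) else "")
            + f" | chains: {self.draws.n_chains} x {self.draws.n_draws} kept draws"
            + f" | converged (all monitored R-hat < {self.rhat_threshold}): {self.converged}\n"
        )
        return head + t.to_string(float_format=lambda x: f"{x:8.4f}")

    def save_summary(self, path, delimiter=","):
        self.summary_table.to_csv(path, sep=delimiter)
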