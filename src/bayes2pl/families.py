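"""Hyperprior families and named specifications for the item-parameter scales.

The hierarchical 2PL places a prior on the scales (tau_alpha, tau_beta) of
the item parameter distribution.  Three families are supported for the
optimized (non-centered) model — half-Cauchy, Exponential and
inverse-Gamma — each in four named specifications ranging from weakly
informative to noninformative:

===========  =============== ================ =============== ================
family       WI1             WI2              NI1             NI2
===========  =============== ================ =============== ================
half_cauchy  scale 1         scale 2.5        scale 5         scale 25
exponential  b = 1           b = 0.4          b = 0.2         b = 0.04
inv_gamma    a=3, b=2        a=1, b=0.5       a=1, b=2        a=0.001, b=0.001
===========  =============== ================ =============== ================

For the Exponential family ``b`` is the inverse scale (rate), so the
implied prior mean of tau is ``1/b``.  A fourth family tag,
``inverse_wishart``, identifies the standard centered comparator model in
which the full item covariance matrix receives an IW(3, I) prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["HyperpriorConfig", "table_specifications", "SPEC_LABELS"]

SPEC_LABELS = ("WI1", "WI2", "NI1", "NI2")

# family -> label -> params
_TABLE = {
    "half_cauchy": {
        "WI1": {"location": 0.0, "scale": 1.0},
        "WI2": {"location": 0.0, "scale": 2.5},
        "NI1": {"location": 0.0, "scale": 5.0},
        "NI2": {"location": 0.0, "scale": 25.0},
    },
    "exponential": {
        "WI1": {"rate": 1.0},
        "WI2": {"rate": 0.4},
        "NI1": {"rate": 0.2},
        "NI2": {"rate": 0.04},
    },
    "inv_gamma": {
        "WI1": {"shape": 3.0, "scale": 2.0},
        "WI2": {"shape": 1.0, "scale": 0.5},
        "NI1": {"shape": 1.0, "scale": 2.0},
        "NI2": {"shape": 0.001, "scale": 0.001},
    },
}

_FAMILY_ALIASES = {
    "half_cauchy": "half_cauchy",
    "halfcauchy": "half_cauchy",
    "cauchy": "half_cauchy",
    "exponential": "exponential",
    "exp": "exponential",
    "inv_gamma": "inv_gamma",
    "inverse_gamma": "inv_gamma",
    "invgamma": "inv_gamma",
    "inverse_wishart": "inverse_wishart",
    "inv_wishart": "inverse_wishart",
}


@dataclass(frozen=True)
class HyperpriorConfig:
    """Variance-component hyperprior: a family plus its hyperparameters.

    Parameters
    ----------
    family : str
        One of ``half_cauchy``, ``exponential``, ``inv_gamma``,
        ``inverse_wishart`` (aliases accepted).
    params : dict
        Family-specific hyperparameters; all strictly positive except the
        half-Cauchy location (fixed at 0 in every named specification).
    label : str or None
        Named specification ("WI1", "WI2", "NI1", "NI2") if the config was
        built from the specification table.
    lkj_eta : float
        Shape of the LKJ prior on the item-parameter correlation
        Cholesky factor (eta=2 mildly favors small correlations).
    scale_is_variance : bool
        If True, normal priors written N(0, 2) are read with the second
        argument as a variance rather than an SD.
    ig_on_variance : bool
        If True, the inverse-Gamma prior is placed on tau^2 instead of tau.
    """

    family: str
    params: dict = field(default_factory=dict)
    label: str | None = None
    lkj_eta: float = 2.0
    scale_is_variance: bool = False
    ig_on_variance: bool = False

    def __post_init__(self):
        fam = _FAMILY_ALIASES.get(str(self.family).lower())
        if fam is None:
            raise ValueError(f"unknown hyperprior family: {self.family!r}")
        object.__setattr__(self, "family", fam)
        for key, val in self.params.items():
            if key != "location" and not val > 0:
                raise ValueError(f"hyperparameter {key}={val} must be > 0")

    @classmethod
    def from_label(cls, family: str, label: str, **kwargs) -> "HyperpriorConfig":
        """Look up a named specification (WI1/WI2/NI1/NI2) for a family."""
        fam = _FAMILY_ALIASES.get(str(family).lower())
        if fam not in _TABLE:
            raise ValueError(f"no named specifications for family {family!r}")
        label = str(label).upper()
        if label not in _TABLE[fam]:
            raise ValueError(f"unknown specification label {label!r}; expected one of {SPEC_LABELS}")
        return cls(family=fam, params=dict(_TABLE[fam][label]), label=label, **kwargs)

    @property
    def tau_scale(self) -> float:
        """Scale multiplier of the uniform-auxiliary transform.

        half-Cauchy: the Cauchy scale sigma; Exponential: 1/rate (the
        prior mean of tau).  Not defined for inverse-Gamma, whose tau is
        sampled directly.
        """
        if self.family == "half_cauchy":
            return float(self.params["scale"])
        if self.family == "exponential":
            return 1.0 / float(self.params["rate"])
        raise ValueError(f"family {self.family!r} has no auxiliary-transform scale")


def table_specifications(family: str | None = None):
    """All named (family, label) hyperprior configs, optionally one family.

    Returns a list of :class:`HyperpriorConfig` in table order; with the
    default ``family=None`` all 12 (3 families x 4 specifications).
    """
    fams = [_FAMILY_ALIASES[family.lower()]] if family else list(_TABLE)
    return [HyperpriorConfig.from_label(f, lab) for f in fams for lab in SPEC_LABELS]
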