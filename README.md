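# bayes2pl

Small-sample calibration of the two-parameter logistic (2PL) item response
model with hierarchical Bayesian estimation, plus the standard comparators
used in parameter-recovery research.

## Who this is for

Psychometricians and test developers who need item parameters from
dichotomous response data collected on far fewer respondents than the
N ≥ 500 usually recommended for the 2PL — classroom exams, pilot studies,
small clinical instruments — and methodologists running recovery
simulations on such designs.

## The model

The 2PL gives the probability that person *j* answers item *i* correctly as

    P(y_ij = 1 | θ_j, α_i, β_i) = logistic(α_i (θ_j − β_i)),

with ability θ_j ~ N(0, 1), discrimination α_i > 0 and difficulty β_i.
The hierarchical model pools information across items by placing a
bivariate prior on ξ_i = (log α_i, β_i) with grand means (μ_α, μ_β),
scales (τ_α, τ_β), and a correlation matrix Ω.  Three design choices make
the implementation robust in small samples:

* **separation strategy** — Σ = diag(τ) · Ω · diag(τ) with independent
  priors on the scales and an LKJ(2) prior on the Cholesky factor of Ω,
  instead of a single inverse-Wishart prior on Σ;
* **non-centered parameterization** — only z-scores ξ̃_i ~ N(0, 1) are
  sampled and the item parameters are recovered as
  ξ_i = diag(τ) L_Ω ξ̃_i, removing the funnel-shaped dependence between
  items and hyperparameters from the posterior geometry;
* **bounded auxiliaries for the scales** — τ = s·tan(u) with
  u ~ U(0, π/2) gives a half-Cauchy(0, s) prior, τ = s·(−log u) with
  u ~ U(0, 1) an Exponential(mean s) prior, avoiding heavy-tailed raw
  coordinates; an inverse-Gamma prior directly on τ is also available.

Each scale hyperprior family comes in four named specifications
(WI1, WI2, NI1, NI2) from weakly informative to noninformative.
Comparators: the centered hierarchical 2PL with Σ ~ IW(3, I), the
nonhierarchical 2PL (α ~ logN(0,1), β ~ N(0,2)), and marginal maximum
likelihood via Bock–Aitkin EM with an inadmissibility screen.  Posteriors
are sampled with an adaptive Hamiltonian Monte Carlo engine using analytic
gradients (three chains of 4000 iterations, 1000 burn-in, by default) and
summarized with posterior means, 95% highest-density intervals, classic
Gelman–Rubin R̂ (convergence declared when all monitored R̂ < 1.05) and
effective sample sizes.

## Worked example

```python
import numpy as np
from bayes2pl import (ChainSpec, GeneratingCondition, Hierarchical2PL,
                      HyperpriorConfig, generate_dataset)

ds = generate_dataset(GeneratingCondition(
    n_persons=100, n_items=25, tau_pair=(0.25, 0.90), rho=0.3, seed=42))
print(ds.items.beta.std(ddof=1))                       # 0.9
print(np.corrcoef(ds.items.alpha, ds.items.beta)[0, 1])  # 0.30000000000000043

model = Hierarchical2PL(ds.responses,
                        HyperpriorConfig.from_label("exponential", "WI2"))
res = model.fit(ChainSpec(n_chains=3, n_iterations=1500, n_burnin=500, seed=1))
print(res.converged)                                   # True
print(res.summary_table.loc["tau_beta", "mean"].round(3))  # 1.012
print(np.corrcoef(res.posterior_mean("beta"), ds.items.beta)[0, 1].round(3))
# 0.969
```

The generator reproduces the requested item-parameter spread (SD of β) and
the α–β correlation *exactly* — they are enforced by construction, not in
expectation — so every simulated dataset sits precisely at its design
condition.  The fitted scale τ̂_β = 1.01 against a true 0.90 and the 0.969
correlation between estimated and true difficulties show the partial
pooling recovering item parameters from only 100 respondents.

The same functionality is available from the shell:

```
bayes2pl generate --n 100 --k 25 --tau 0.25,0.90 --rho 0.3 --seed 42 --out data/
bayes2pl fit --data data/responses.csv --model oh2pl --family exponential \
    --spec WI2 --out summary.csv
bayes2pl study --config study.yaml --out results/
```

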