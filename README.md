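# mutrescue

Quantitative analytics and exact stochastic simulation of **evolutionary
rescue on mutator backgrounds** in a continuously deteriorating environment.

## The problem

A wildtype population of maximum size `K` faces an environment whose quality
declines along a Hill function centred at time `θ` with steepness `n`: the
wildtype's relative growth rate falls as `1/(1 + (t/θ)^n)` while a *rescue
allele* — reached by a fraction `r` of all genomic mutations — gains growth
as `(t/θ)^n/(1 + (t/θ)^n)`. Once the wildtype's growth rate drops below the
per-capita death rate `g`, the population declines toward extinction unless
a rescue lineage escapes stochastic loss and sweeps.

A second, completely linked locus modifies the genomic mutation rate: a
**mutator** has rate `ν′ = F·ν` (or `ν + Δ` in the additive variant) versus
the wildtype's `ν`. Higher mutation rates buy more access to the rescue
locus (`μ′ = r·ν′ > μ = r·ν`) but carry a linear fitness cost
`max(0, 1 − ν/ν_c)` that reaches lethal mutagenesis at the critical rate
`ν_c`. Mutators either **emerge de novo** from wildtype births at rate
`μ_M = E·r·ν`, or **pre-exist** at a fraction `α` of the population. The
package answers two linked questions: how much do mutators raise the chance
of rescue, and how likely is an environmental crisis to *promote* mutators
(a rescue sweep on the mutator background)?

## What the library computes

- **Deterministic dynamics** (`deterministic_dynamics`): logistic decline of
  `N_W(t)` and `N_M(t)` (or `E[N_M](t)` for de novo emergence) under the
  shared carrying capacity.
- **Fixation probabilities** (`rescue_analytics`): for a rescue mutant
  founded as one copy at time `t₀`,

      P_fix(t₀) = 1 / (1 + g ∫_{t₀}^∞ e^{ρ(t)} dt),
      ρ(t) = ∫_{t₀}^{t} [g − f_eff(u)] du,

  with `f_eff` the rescue lineage's growth damped by competition
  `1 − N(t)/K`. For a de novo mutator founder the two-type
  (mutator → rescued-mutator) backward extinction equations are integrated
  numerically.
- **Rescue probabilities**: e.g. the wildtype channel

      Pr_W = μ ∫ P_fixW(u) · N_W(u) f_W(u) [1 − N(u)/K] du,

  combined as `Pr_all = Pr_W + (1 − Pr_W)·Pr_M`, and the **mutator
  advantage** `(Pr_all − Pr_W0)/Pr_W0` relative to the mutator-free baseline
  `Pr_W0`. For pre-existing mutators without mutation cost the advantage
  approaches `(F − 1)·α`.
- **Exact stochastic simulation** (`stochastic_sim`): a Gillespie sampler of
  the four-type birth–death–mutation process (time-dependence handled
  exactly by Poisson thinning), with outcome classification
  (extinct / rescued by wildtype / rescued by mutator / persisted), mutator
  fixation flags, and seeded Monte-Carlo branching oracles used to validate
  every analytic fixation profile.
- **Sweeps and CLI** (`experiments_cli`): grid sweeps over
  `ν, F, n, E, α, θ` with CSV + JSON-sidecar output.

## Worked example

```python
from mutrescue import rescue_result
from mutrescue.experiments_cli import make_params

params = make_params(nu=1e-3, F=5.0, n=10.0, E=2000.0, theta=500.0)
res = rescue_result(params, "de_novo")
print(f"PrW0={res.PrW0:.5f} PrW={res.PrW:.5f} PrM={res.PrM:.5f} "
      f"Prall={res.Prall:.5f} advantage={res.advantage:.4f}")
```

prints

```
PrW0=0.00951 PrW=0.00932 PrM=0.00093 Prall=0.01024 advantage=0.0769
```

i.e. at a wildtype rate of `10⁻³` per genome per generation, allowing
strength-5 mutators to emerge (E = 2000) slightly *lowers* rescue through
the wildtype channel (`PrW < PrW0`, emergence diverts wildtype births) but
opens a mutator channel (`PrM`) that raises overall survival by ≈7.7%.

The same pipeline from the shell:

```bash
mutrescue analytic --nu 1e-3 --f 5 --n 10 --e 2000 --theta 500
mutrescue simulate --nu 1e-3 --k 1000 --r 2e-3 --n-replicates 2000 --seed 1
mutrescue sweep my_sweep.yaml --output sweep.csv
```

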