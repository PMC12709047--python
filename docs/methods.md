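# Methods

## Model

Four lineage types are tracked: wildtype (W), mutator (M), and rescue
mutants on either background (RW, RM). Relative growth rates combine a
Hill-shaped environmental factor with a linear mutation-load cost:

    f_W(t)  = c(ν)  / (1 + (t/θ)^n)         c(ν)  = max(0, 1 − ν/ν_c)
    f_RW(t) = c(ν)  · (t/θ)^n / (1 + (t/θ)^n)
    f_M(t)  = c(ν′) / (1 + (t/θ)^n)          ν′ = F·ν  (or ν + Δ)
    f_RM(t) = c(ν′) · (t/θ)^n / (1 + (t/θ)^n)

All individuals die at rate `g` and births are damped by logistic
competition `1 − N/K` on the total population. Mutation happens at birth
only, as mutually exclusive offspring outcomes: a wildtype birth yields a
mutator with probability `μ_M = E·r·ν`, a rescue mutant with probability
`μ = r·ν`, otherwise a faithful copy; a mutator birth yields a rescued
mutator with probability `μ′ = r·ν′`. Rescue types breed true; there is no
back mutation and mutators do not mutate further at the modifier locus.

The rising and falling Hill exponents may differ (`n_rise`), but default to
the same `n`. A `constant` environment mode freezes all growth functions at
their t = 0 values (so rescue lineages have zero growth); it models the
no-stress control. Population sizes in the deterministic module are
continuous; extinction and drift belong to the stochastic module.

### Parameters, units, defaults

| symbol | meaning | default |
|---|---|---|
| ν | wildtype genomic mutation rate (per genome·generation) | 10⁻³ |
| ν_c | critical rate, lethal mutagenesis | 1 |
| F | mutator strength (fold-elevation) | 5 |
| r | fraction of genomic mutations hitting the rescue locus | 2·10⁻⁴ |
| E | mutator emergence factor (μ_M = E·r·ν) | 500 |
| α | pre-existing mutator fraction | 0.05 |
| K | carrying capacity | 10⁴ |
| g | per-capita death rate (per generation) | 0.1 |
| n | environmental-change speed (Hill exponent) | 2 |
| θ | midpoint of deterioration (generations) | 500 |

The calibration follows microbial (E. coli-like) magnitudes: ν ≈ 10⁻⁴–1,
one average-sized rescue gene out of ~5000 (r = 2·10⁻⁴), modifier-locus
target up to 2000-fold the rescue target, mutator strengths 2–80, and a 5%
mutator inoculum as used in competition experiments.

## Deterministic dynamics

De novo scenario (expected mutator population competes for capacity):

    dN_W/dt = [f_W(t)(1 − (N_W+N_M)/K)(1 − μ_M) − g] N_W
    dN_M/dt = μ_M f_W(t)(1 − (N_W+N_M)/K) N_W + [f_M(t)(1 − (N_W+N_M)/K) − g] N_M

Pre-existing scenario: the same system without the emergence terms and with
initial conditions `N_W(0) = (1−α)K(1−g/f_W(0))`, `N_M(0) = αK(1−g/f_W(0))`.
The mutator-free baseline used for `Pr_W0` is the α = 0 / μ_M = 0 reduction
(identical in both scenarios).

Integration uses LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰ (populations traverse
many orders of magnitude near extinction). The horizon stops when both
`f_W < 10⁻⁸ f_W(0)` and `N_W + N_M < 10⁻³` individuals (terminal event),
capped at 50 θ; beyond that point every downstream integrand is numerically
zero. Dense output is sampled on ~4000 points: 2000 across the full horizon
plus a 2000-point refinement on `[0.2 θ, 5 θ]` where the environmental
transition concentrates all the action. Initial conditions default to the
pre-change equilibrium `K(1 − g/f_W(0))` but are overridable (`initial=`)
for burn-in studies.

## Fixation probabilities

For a rescue mutant founded at `t₀` in a resident background `N(t)`,

    P_fix(t₀) = 1 / (1 + g ∫_{t₀}^∞ e^{ρ(t)} dt),   ρ(t) = ∫_{t₀}^t [g − f_eff(u)] du

with `f_eff = f_R·(1 − N/K)`. Numerics: `ρ` is accumulated by trapezoid on
the trajectory grid; the outer integral uses the **exponential segment
rule** — each segment contributes `Δt·e^{R_i}(e^{ΔR}−1)/ΔR`, exact for
piecewise-linear `ρ` — because plain trapezoid on `e^ρ` would require steps
far below `1/(f−g)`. Everything is evaluated in log space (reverse
`logaddexp` accumulation), so exponents of ±hundreds are harmless, and the
tail beyond the horizon is added in closed form with end-of-grid rates held
constant: `e^{ρ(T)}/(f_end − g)` if `f_end > g`, else the integral diverges
and `P_fix ≡ 0`. With constant rates this machinery reproduces `1 − g/f` to
machine precision (tested at 10⁻⁶).

For a **de novo mutator founder** the relevant probability is that its
lineage produces a rescued-mutator line that fixes. We integrate the
backward equations of the two-type time-inhomogeneous branching process in
terms of success probabilities `p_M = PfixM`, `p_R` (fixation of one RM):

    dp_M/dt = −[(b_M − g − b_M μ′) p_M + b_M μ′ p_R − b_M(1−μ′) p_M² − b_M μ′ p_M p_R]
    dp_R/dt = −[(b_R − g) p_R − b_R p_R²]

with `b_M = f_M(1−N/K)`, `b_R = f_RM(1−N/K)`, terminal values `p_M(T) = 0`
and `p_R(T) = max(0, 1 − g/b_R(T))`. The success-probability formulation is
chosen over extinction probabilities because `PfixM` can be ~10⁻⁵ and
`1 − u` would lose precision. Backward-in-time integration is the stable
direction for this system in both sub- and supercritical regimes. Two
independent validations: the `p_R` component must agree with the integral
formula (tested at 10⁻³ relative), and both profiles must agree with
seeded Monte-Carlo branching simulations within 3 binomial SE.

## Rescue probabilities

Each channel integrates founder rate × fixation probability on the shared
trajectory grid (trapezoid; the integrand varies on the θ time scale, not
the `1/(f−g)` scale, so no exponential rule is needed):

    Pr_W        = μ   ∫ PfixW(u)  N_W f_W  (1 − N/K) du
    Pr_M (de novo)     = μ_M ∫ PfixM(u)  N_W f_W  (1 − N/K) du
    Pr_M (pre-existing) = μ′  ∫ PfixRM(u) N_M f_M  (1 − N/K) du
    Pr_all = Pr_W + (1 − Pr_W) Pr_M

Probabilities below 10⁻³⁰ are reported as exactly 0 (quadrature noise
floor). The advantage `(Pr_all − Pr_W0)/Pr_W0` is undefined at `Pr_W0 = 0`
(NaN + flag, never a silent number); sweeps also emit the absolute
difference `Pr_all − Pr_W0`, which stays meaningful when `Pr_W0` is tiny.

## Stochastic simulator

The four-type process is sampled **exactly** by Poisson thinning: between
accepted events the state is constant, so `N·(c(ν)·(1−N/K) + g)` bounds the
total rate at all later times (falling Hill factors only decrease; rising
ones never exceed 1). Candidate times are exponential at the bound;
candidates are accepted with probability actual/bound. No rate freezing or
tau-leaping is used; with frozen (constant) rates the accepted inter-event
waits are verifiably exponential (KS test in the suite).

Replicates start from the rounded equilibrium split (α rounds the mutator
count up to ≥1 when α > 0) and end at extinction, at rescue declaration
(rescue types ≥ ⌈0.1 K⌉, a bounded-runtime stand-in for true absorption),
or at `t_end = 6 θ` (where `f_W ≈ 0` for all n ≥ 1 used here). Outcomes:
`extinct`, `rescued_by_wildtype` / `rescued_by_mutator` (majority of rescue
types at declaration), and `persisted` — alive at `t_end` with no rescue
carriers, which arises in constant-environment controls where the wildtype
simply survives; the three-way classification would otherwise be forced to
mislabel such runs. `mutator_fixed` flags termination states in which every
survivor carries the mutator background. Per-replicate RNG substreams
derive from one master seed (SeedSequence), so ensembles are bit-reproducible.

The **branching oracle** simulates single founder lineages against the
deterministic trajectory (no feedback) and declares fixation once
`k·ln(b_R/g) > 20` for current rescue count `k` — residual extinction
probability ≤ (g/b_R)^k ≤ e⁻²⁰, a valid bound because the effective rescue
growth rate is nondecreasing in time (rising Hill × shrinking resident
population) in the deteriorating scenarios where the oracle is used.

## Desk-scale validation choices

Analytic-vs-simulation comparisons run at `K = 10³` with `r` scaled ×10 so
that `K·μ` (and hence the expected number of rescue founders) matches the
`K = 10⁴` calibration; 5000 replicates give 3-SE resolution of ~1% on
rescue frequencies. The no-stress control and the environment-speed
experiment use θ = 200 and 2000–3000 replicates per point; for the
speed experiment the share of rescues carried by pre-existing mutators is
compared at ν = 10⁻², where the share spans 0.02→0.09 across n ∈ {1,2,5,10}
and is therefore resolvable at 3000 replicates (at ν = 10⁻³ the same
monotone trend exists analytically but rescued counts are too small to
order reliably at this replicate budget).

What the generator does *not* emulate: real populations are not at perfect
equilibrium at t = 0 (a burn-in knob exists but defaults to equilibrium),
there is no recombination, no multiple coexisting mutator strengths, no
back mutation, and no density-dependent death. Passing tests therefore
validate the mathematical machinery under the model's own assumptions, not
those biological complications.

## Known limitations

- The branching approximation ignores competition between doomed wildtype
  rescue lineages and mutator rescue lineages; at `K = 10³` the agreement
  with simulation is within Monte-Carlo error, but very small `K` would
  strain it.
- `Pr_all` treats the two channels as mutually exclusive in a single
  surviving sweep; simultaneous near-fixation of both is not modeled.
- The rescue-declaration threshold (0.1 K) is a runtime/exactness
  trade-off; it is configurable and outcome frequencies are insensitive to
  it well above demographic-noise scales.
- For very slow environmental change (n ≲ 1) with late horizons, `t_end =
  6 θ` truncates rescue events that would occur later; comparisons there
  are internally consistent (simulation vs. simulation) but not exhaustive.
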