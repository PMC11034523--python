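# Methods

This note records the models implemented in `twopac`, the choices made
where the design was genuinely open, and what the simulations do and do
not establish.

## The two-phase survival model

Ageing is modelled as two consecutive phases separated by an abrupt,
one-way transition (the "Smurf" transition; reversion is not modelled).
The phenotype is treated as binary even though the underlying dye leakage
is graded.  The model is specified by

- `a` — Smurf-appearance slope (fraction/day), the speed at which the
  proportion of Smurfs among the living grows;
- `t0` — age of the first Smurf (days);
- `k` — Smurf mortality rate (/day), age-independent.

The Smurf proportion among the living is `p(t) = clip(a(t − t0), 0, 1)`.
The clip is our choice: the linear law cannot exceed 1, and capping it is
the only handling consistent with the hazard-plateau argument.  The
population hazard is `k p(t)` and survival is
`S(t) = exp(−k ∫₀ᵗ p(u) du)`, evaluated in closed form piecewise
(plateau, Gaussian shoulder, exponential tail).  Piece boundaries are
closed on the left; the pieces agree at the boundaries to machine
precision.

The slope/intercept line form `p = a t + b` (with `b = −a t0`) is
supported as a constructor and preserved exactly on round trip.  A
positive intercept (`t0 < 0`) is allowed and means the cohort already
contains Smurfs at `t = 0`; the closed forms integrate the hazard from 0
in that case.  All times are cohort ages in days; all rates are per day.

`k` has no published value in the source material for this package;
`k = 0.3/day` (mean Smurf phase of ~3.3 days, consistent with transition
2–3 days before death in female flies) is a package convention used as a
simulation default, not a measured constant.

### Individual-level transition rate

The per-individual transition hazard consistent with both the linear
proportion law and constant Smurf mortality is
`λ(t) = a/(1 − p) + k p`.  Plugging λ into the two-type balance
`N' = −λN`, `S' = λN − kS` reproduces `p(t)` exactly; this is a
consistency construction, not an independently published quantity.  λ
diverges at saturation; the simulator converts any surviving individual
at `t_sat` deterministically (a measure-zero event).

### Signal-mixture deconvolution

A population-average signal at Smurf proportion `s` is
`mixed = s·smurf + (1−s)·nonsmurf`; the non-Smurf component is recovered
as `(mixed − s·smurf)/(1 − s)`, undefined at `s = 1` (no non-Smurfs left
to measure).

## Cohort simulation

Transition ages are drawn by inverse-transform sampling of the cumulative
transition hazard, which has the closed form (with `β = k/2a` and `p₀`
the proportion at first exposure)

`Λ(p) = −log((1−p)/(1−p₀)) + β(p² − p₀²)`,

inverted by vectorised bisection on `p` to better than 1e−12; the Smurf
sojourn is an independent exponential of rate `k`.  This samples the joint
law exactly — the marginal death distribution *is* the closed-form
survival, with no discretisation bias — which is why a Kolmogorov–Smirnov
comparison against the closed form is a valid end-to-end check of the
simulator.

Randomness layout: one PCG64 stream supplies two uniforms per individual
in row-major order, so individual `i` always consumes draws `2i, 2i+1`;
enlarging the cohort appends individuals without reshuffling earlier
ones.

The cross-sectional assay is exhaustive and noiseless by default;
`subsample=m` scores only `m` living individuals without replacement
(hypergeometric counts) to emulate finite assay effort.

## Fitting

The headline loss is unweighted least squares on survival fractions (the
quantity longevity plots display); likelihood-based fitting from raw death
times is used only as an independent cross-check in the test suite (via
lifelines).  Optimisation is multi-start Levenberg–Marquardt on
log-transformed positive parameters (tolerances 1e−15, ≤10,000
evaluations per start), with a Nelder–Mead polish for the piecewise
two-phase model whose residuals have kinks at `t0` and `t_sat`.  AIC is
computed as `n·ln(SSE/n) + 2p` under a Gaussian-residual surrogate and is
a heuristic ranking device, not an inferential statement.

Parameterisations: Gompertz hazard `μ(t) = a0·e^{gt}`; Weibull survival
`S(t) = exp(−a·t^k)`.  Published parameter values are used as round-trip
generating truths within these conventions only — no claim is made that
other software's conventions yield numerically identical values.

**Identifiability.**  On a survival curve that ends before Smurf
saturation (the common case: the cohort dies while `p < 1`), the
two-phase survival depends on `(a, k)` only through the product `k·a`, so
the free fit is degenerate along that ridge.  The free fitter therefore
optimises `(m = k·a, t0, k)`: the identified quantities converge always,
and on degenerate data the reported `k` remains near its conventional
starting value instead of drifting to absurd ridge points.  When the
Smurf mortality is known, `k_mode="fixed"` fits `(a, t0)` and recovers
them fully.  Parameter-recovery claims in the tests respect this: free-fit
recovery of all three parameters is asserted only on curves whose
exponential tail is visible (`k/2a` small enough that saturation survival
exceeds the sampling floor).

**Smurf-line regression.**  The line `p = a t + b` is fitted by weighted
least squares (weights = living individuals scored).  The linear law only
holds between onset and saturation, so clipped ages are excluded on both
sides: leading ages before the first observed Smurf (where the empirical
proportion is pinned at 0 but the line is negative — keeping them biases
the intercept toward zero and flattens the slope) and saturated ages
(`p = 1`).  Benchmark experiments assay daily while at least ~10% of the
cohort is alive; deeply depleted ages contribute almost no information
and couple realised weights to proportion errors.

## Birth–death model of the evolution of senescence

Each haploid, asexually reproducing individual carries heritable traits
`x_b` (age at which fertility ends; fecundity intensity `i_b`) and `x_d`
(age at which mortality risk becomes non-zero; mortality intensity
`i_d`).  Newborns copy the parent; each trait independently mutates with
probability `p_mut` by a centred Gaussian of SD `sigma_mut`, truncated at
zero (traits are ages).

Resource limitation is required to bound the population, but its
functional form is a modelling choice.  Two are implemented:

- **fecundity regulation** (default): birth rate `i_b·max(0, 1 − N/K)`
  while fertile, death rate `i_d` only once senescent.  This preserves
  the defining property that mortality risk is strictly zero before
  `x_d`.
- **mortality regulation**: birth rate `i_b` while fertile, death rate
  `i_d·1{age > x_d} + c·N` for everyone (classical logistic
  competition).

The default matters.  Under mortality regulation the equilibrium crowding
death rate is of the same order as `i_b` (≈1.9/day at the standard
settings), so the expected lifespan (~0.5 d) is far shorter than
day-scale trait values; selection on both traits is then exponentially
suppressed and the trait pair performs a nearly neutral random walk — in
our replicate experiments the trait gap wandered with either sign and no
trade-off emerged.  Under fecundity regulation lifespans are set by the
traits themselves, selection stays active, and the model's qualitative
behaviour appears robustly: both traits creep upward indefinitely (only
infinite time would take them to infinity), while their difference
`x_b − x_d` settles at a small positive value governed by the
intensities (≈ln 2/i_d ≈ 0.35 d at the defaults); fertile periods evolve
shorter as `i_b` grows with no coupling coded anywhere; and
fast-turnover configurations move their trait means several-fold faster
than slow ones at the same mutation rate.

Default configuration: `i_b = i_d = 2/day`, `K = 667` (equilibrium
population ≈500 at the founder traits), `p_mut = 0.1`,
`sigma_mut = 0.5 d`, 500 founders with `x_b = x_d = 2 d`.

**Schedulers.**  The exact scheduler is event-driven: individual rates
are piecewise constant between events and age-threshold crossings, so the
next event is sampled from the current total rate and re-sampled at the
earliest crossing (valid by memorylessness).  The default fast scheduler
uses a fixed step with exact per-step probabilities `1 − exp(−r·dt)` and
an adaptive `dt = 0.05 / max per-individual rate`; its only bias is from
threshold crossings and population-size changes within a step, and it is
validated against the exact scheduler statistically on a small
configuration.  Cumulative births and deaths are recorded so that
`n0 + births − deaths = N` holds exactly at every recorded time.

**Diagnostics.**  `trait_gap_summary` time-averages the mean gap over a
trailing window (default last quarter).  `exploration_speed` averages
`|Δ mean x_b| / Δt` over non-overlapping windows — a measure of how fast
a lineage's trait mean moves, whether by drift or selection response.

### What the simulations do and do not show

- The positive trait gap, its agreement from opposed founder orderings,
  the `x_b`–`i_b` trade-off direction and the exploration-speed ordering
  are demonstrated at population size ≈500–700, horizons of 150–800
  days, and 5–10 replicate seeds — desk-scale stand-ins for asymptotic
  claims.  Problem sizes were chosen as the smallest at which the
  relevant signal clearly exceeds replicate noise.
- The trait gap is only *quasi*-stationary: trait means keep creeping
  upward, and the replicate-mean gap of 10 seeds fluctuates by several
  tens of percent over a trailing quarter at these horizons.  We
  therefore test positivity, sign-stability over the equilibrated tail,
  and cross-condition agreement — not a tight numerical drift bound.
- Convergence from founders with `x_d` far above `x_b` is metastable:
  selection culls the sub-fertile tail of the `x_d` cloud, dragging the
  whole cloud upward in lockstep with `x_b` for very long times (initial
  orderings more than ~1 day apart can persist for thousands of
  simulated days).  The opposed-founder experiments therefore start
  within about a day of ordering difference; the strong-opposition
  regime is an open scaling question, not a package defect.
- No claim is made about the exact analytic long-time limit of the gap;
  only its sign, stability and parameter dependence are tested.

## Synthetic data and realism

All test inputs are generated by the package's own simulators.  The
cohort simulator emulates an idealised longevity experiment: no
censoring, no escapers (every individual passes through the Smurf phase),
no sex structure, no batch effects, and a noiseless (or binomially
subsampled) assay.  Passing tests therefore establish internal
consistency of the implementation and recoverability of parameters under
the model's own assumptions — not that real cohorts follow the two-phase
law.  The published real-data fit quality (R² on an experimental
longevity curve) cannot be reproduced here because the underlying raw
cohort data are not distributed; the corresponding benchmark is exercised
as a self-fit precision bound instead.

## Numerical conventions

- Ages validated finite (and non-negative where they are cohort ages);
  degenerate inputs (empty cohorts, single-time assays, curves not
  reaching 50% mortality, zero-variance observations) raise
  `ValueError` with a descriptive message.
- Bisection inversions run to interval widths below 1e−12 days.
- Survival-curve containers enforce strictly increasing times and
  non-increasing fractions (tolerance 1e−9 for floating-point noise).
- Fit reports serialise parameters as decimal strings (`repr`) so JSON
  round trips are exact; every report carries a schema version.
- CSV only: comma-separated, UTF-8, dot decimal, header required, days
  as the only time unit.
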