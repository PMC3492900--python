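# Methods

## The model

The habitat is a rectangular lattice (default 51 × 51 = 2601
locations), each location a ~1 µm² microenvironment holding at most one
pathogen cell plus the local concentrations of two product variants:
the drug-sensitive form made by sensitive cells and the drug-proof form
made by resistant cells. Time advances in discrete steps; one step is
nominally 40 minutes (a typical *Pseudomonas aeruginosa* generation
time at body temperature), but the duration is metadata only — nothing
in the dynamics depends on it.

A cell is characterized by a vitality *v* ∈ [0, 1] (its propensity to
survive and divide) and a binary resistance state. Each step proceeds
as:

1. **Release and drug action.** Every living cell deposits
   `release_amount` (default 1.0) of its variant at its own location.
   The drug destroys fraction *d* ∈ [0, 1] (the dose) of the sensitive
   variant at release; the resistant variant is untouched. Because the
   fields are fully cleared at the end of each step, degrading at
   release is equivalent to degrading the standing sensitive pool; the
   form chosen makes "full dose, maximal effect" literal: at *d* = 1 a
   sensitive cell contributes nothing.
2. **Diffusion.** Each field takes one synchronous diffusion step: for
   every pair of von Neumann (4-)adjacent locations, (T/4)·(cᵢ − cⱼ)
   moves down the gradient, all fluxes computed from the pre-step
   field. Boundaries are reflecting (no flux), so mass is conserved
   exactly, and the update `c(1 − T·deg/4) + (T/4)·Σneighbours` keeps
   every concentration non-negative for all T ∈ [0, 1]. T is the
   private↔public axis: a producer retains 1 − T of a fresh unit
   (T = 0, cell-intrinsic target; T = 1, fully shared target).
3. **Cell events.** Living cells are visited in a fresh uniform random
   permutation. Each reads the post-diffusion total concentration [p]
   at its location, gains Δv = min([p], 1)·(1 − v) (the clamp keeps the
   vitality a probability ingredient if a location transiently holds
   more than one unit), then dies with probability 1 − v. A survivor
   with at least one vacant neighbour divides with probability 0.9;
   both daughters receive v/2, each independently flips resistance
   state with probability μ = 10⁻³ (symmetric), one daughter replaces
   the parent, the other takes a uniformly chosen vacant neighbour.
   Deaths free locations immediately and daughters occupy them
   immediately, visible to cells later in the permutation; daughters
   are not themselves updated until the next step.

A run starts from a full lattice of drug-sensitive cells with
v ~ Uniform(0, 1), burns in (drug on) until the first resistance
mutation arises, then records per-step statistics for `record_window`
(default 1000) further steps. Runs in which the population dies out
before any mutation, or in which no mutation arises within
`max_burn_in` steps, are reported as aborted, never silently averaged.

### Event-order choice

Scheduling is the one place the source dynamics are genuinely open: a
strictly per-cell order in which each cell reads its own location right
after releasing there would give every producer full access to its own
product before any sharing, making even a T = 1 target partly private.
We therefore release for all cells, diffuse once, and only then run the
per-cell loop — this is what makes the transfer coefficient's endpoints
exact (T = 0: producer keeps everything; T = 1: producer keeps
nothing).

### Product turnover

Product persistence is a free choice; the default is full per-step
turnover (fields cleared each step), which keeps [p] bounded by local
production and needs no decay constant. A persistence factor
λ ∈ [0, 1] (`field_persistence`, default 0) is exposed for sensitivity
analysis but is not part of the reference conditions.

## Statistics

Selection for resistance per step is summarized by the covariance
decomposition cov(r, v) = sd(r)·sd(v)·corr(r, v) with population (÷N)
moments, resistance coded 0/1 and vitality as the fitness proxy. The
correlation is undefined (NaN) when fewer than two cells live or either
variable is constant; window averages use only defined steps (coercing
undefined correlations to 0 would bias the average toward zero exactly
when a sweep has completed). Population size averages over all steps,
counting extinct steps as 0. Constant variables are detected by exact
min=max comparison so that a mathematically zero variance is reported
as exactly zero rather than centering round-off.

Replicate-level inference uses the one-tailed Welch test on per-run
window means (10 runs per condition; sample variances,
Welch–Satterthwaite degrees of freedom, t-distribution tail from
scipy). Comparing run means rather than pooled steps avoids
pseudo-replication. When both samples have zero variance the statistic
is undefined and flagged, not coerced.

Each run's seed comes from
`SeedSequence((base_seed, 1000·T, 1000·dose, replicate))`, an injective
map, so adding conditions never changes existing replicates' streams
and every table is reproducible from one base seed. All randomness in a
run flows through a single generator in a fixed order (permutation,
then five uniforms per visited cell: death, division, placement, two
mutation draws), so a (params, seed) pair reproduces a trajectory bit
for bit; the compiled (numba) per-cell pass is verified bit-identical
against a plain-Python twin in the test suite.

## Parameters

| parameter | default | meaning |
|---|---|---|
| grid | 51 × 51 | habitat; population cap 2601 |
| T | {0, 0.5, 1} | transfer coefficient (dimensionless share) |
| dose | {1.0, 0.75, 0.5} | fraction of sensitive product destroyed |
| reproduction probability | 0.90 | division chance given a vacancy |
| μ | 10⁻³ | per-daughter resistance flip at division |
| release amount | 1.0 | product units per cell per step |
| resistance cost | 0.0 | optional vitality cost of resistance |
| record window | 1000 steps | from the first mutation |
| replicates | 10 | seeds per condition |

The physical reference diffusion coefficient (order 10⁻⁶ cm² s⁻¹ for a
small solute) is recorded as documentation only; the dynamics use the
dimensionless T. A uniform metabolic cost of production is omitted from
the dynamics: every cell produces equally, so it cannot generate
selection among them; the optional `resistance_cost` covers the case
where the resistant variant is costlier, and defaults to 0 so that
selection arises purely from differential access to product.

## What the simulations do and do not show

The generator *is* the study system — there is no external data. Known
dynamical regimes worth understanding before interpreting output:

* **Full dose, private target (T = 0).** Sensitive cells get no product
  ever; the initial population collapses within ~10–15 steps (division
  halves vitality, deaths do the rest). A resistant mutant keeps its
  whole unit, reaches v = 1 in one step, and sweeps into the emptied
  lattice: window-mean resistant frequency ≈ 1, population ≈ 2600.
* **Full dose, public target (T = 1).** A lone resistant mutant keeps
  nothing; establishment requires a nascent cluster to survive on
  mutually shared product and is a near coin flip per run. Runs end
  either extinct (frequency ≈ 0) or swept; this bimodality across the
  10 replicates dominates the between-run variance at T = 1, so the
  directional effects (lower frequency, smaller population at T = 1)
  are robust while the attained Welch p-values fluctuate around 10⁻⁴.
* **Vitality saturation at sub-maximal dose.** With any constant
  [p] = c > 0, 1 − vₙ = (1 − v₀)(1 − c)ⁿ → 0, a cell's remaining
  lifetime death hazard is finite (≈ (1 − v₀)/c), and a full lattice of
  saturated cells freezes: no deaths, no divisions, no further
  mutations. At dose ≤ 0.75 sensitive cells saturate too, so resistance
  spreads only during the initial transient and then freezes near the
  mutation floor — lower dose yields *less*, not more, evolved
  resistance under this parameterization. For the same reason a dose-0
  population generates no data at all (no turnover, hence never a
  mutation), which is why the Welch-calibration check uses a
  same-condition null (two replicate groups from one condition) rather
  than a dose-0 contrast.
* **Correlation windows are asymmetric across T.** At T = 0 the sweep
  completes within ~15 steps, so the resistance–vitality correlation is
  defined only during the crash, when newborn resistant cells still
  carry low inherited vitality; at T = 0.5 some runs hold a sharp
  producer/freeloader vitality split for the whole window. The
  correlation therefore orders cleanly against T = 1 but not between
  T = 0 and T = 0.5 under this nearest-neighbour discretization.

None of this models pharmacokinetics, host immunity, continuous
resistance levels, horizontal transfer, or physical units; conclusions
are about the ordering of conditions inside the model, not about
absolute rates in any real pathogen.

## Problem sizes used by the test suite

The acceptance-level checks run the full 51 × 51, 1000-step-window
experiment at full dose (30 runs). Property and calibration checks use
smaller habitats (11–21 cells on a side) with 50–150-step windows and
half dose, where populations reliably survive to record; the Welch
null calibration uses 50 repetitions of 4-vs-4 run groups at one fixed
condition. These sizes are the package's own choices for sharp, fast
checks; the scientific claims are always evaluated at the reference
conditions above.
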