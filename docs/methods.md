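# Methods

## Model

A finite, well-mixed, asexual population of `N` individuals plays a donation
game gated on phenotype identity. Individual `i` carries `(G_i, S_i, K_i)`:
one expressed phenotype `G_i`, a strategy `S_i`, and a repertoire size `K_i`
(the number of phenotypes it could switch to). Only the expressed phenotype is
visible. A contingent cooperator pays `c` to deliver `b` to every
same-phenotype partner; defectors never donate. Every individual pays a linear
maintenance cost `θ·K_i` for its repertoire. Payoffs are totals over all
pairwise interactions (self-interaction excluded), and fitness is exponential
in payoff, `f = e^{βπ}`; `β = 0` is neutral drift.

Evolution is a frequency-dependent Moran process: one parent is drawn
proportional to fitness, a uniformly random individual among the `N` present
dies, the offspring fills the slot (the offspring cannot die at its own birth
step; the parent can). With probability `μ` the offspring is a combinational
mutant — strategy uniform over `{C, D}`, repertoire uniform over `{1..M}`,
expressed phenotype uniform over its new repertoire — otherwise it inherits
the parental triplet verbatim (clonal expression). Only the two discrete
strategies `C = [1, 0]` and `D = [0, 0]` are representable; the general
Prisoner's Dilemma payoffs are fixed to the donation-game parameterization
(`R = b−c, T = b, S = −c, P = 0`), since interactions are defined entirely by
`b` and `c`.

Phenotype labels form a **nested universe**: a repertoire of size `K`
expresses a uniform label from `{1..K}`. A mutant with `K_Y ≥ K_X` therefore
covers the residents' label surely and matches it with probability
`α_Y = 1/K_Y`; a mutant with `K_Y < K_X` covers it with probability `K_Y/K_X`
first. This is the one labeling convention consistent with both branches of
the strain-replacement rate used by the embedded chain, and the agent-based
simulator uses the same labels so that match statistics reproduce `α = 1/K`.

## Parameters

| name | meaning | units | default |
|------|---------|-------|---------|
| `N` | population size | individuals | 20 |
| `b` | donation benefit | payoff | 1.0 |
| `c` | donation cost (`b > c > 0`) | payoff | 0.3 |
| `beta` | selection intensity | per payoff | 0.1 |
| `theta` | maintenance cost per expressible phenotype | payoff | 0.1 |
| `mu` | mutation probability per birth | — | 0.002 |
| `M` | repertoire cap | phenotypes | 50 |

Defaults are the model's standard study conditions. `M = 50` is the cap used
throughout the analysis; it is a config knob, justified by the fact that
costly repertoires are self-limiting (strains with very large `K` are
selected against whenever `θ > 0`), so the cap only needs to sit above the
selectively relevant range.

## Exact analytics

**Fixation.** During an invasion all mutants share one expressed label and
all residents another (clonal inheritance freezes the match indicator `δ` for
the whole sweep). The two-type payoffs `P_A(i), P_B(i)` are linear in the
mutant count `i`, and the birth-death product formula gives
`φ₁ = (1 + Σ_l Π_{k≤l} T_{k,k−1}/T_{k,k+1})^{−1}`. The ratio collapses to
`e^{β(P_B − P_A)}` (sampling factors cancel), so the implementation
accumulates cumulative sums of `β(P_B − P_A)` and applies log-sum-exp: the
result is exact at `β = 0` (returning `1/N`) and remains finite for `β` of
order 10³ and beyond. An independent oracle (`brute_force_fixation`) solves
the absorbing-chain linear system built directly from the payoff kernel and
is held to agree to 10⁻¹⁰ on randomized small-`N` cases. For defector pairs
the payoff difference is constant in `i` and the formula reduces to the
closed form `(1 − e^{βθΔK}) / (1 − e^{NβθΔK})`, evaluated with `expm1` (plus
a log-space factor for positive exponents) and returning the limit `1/N` at
the neutral point.

**Strain replacement.** The rate of resident strain `X` being replaced by
mutant strain `Y` weights the matched/mismatched fixation probabilities by
the nested-universe match probabilities, with the factor ½ for the mutant's
equally likely strategy. The rate direction follows the reading that the
population *leaves* `X` via the fixation of a single `Y` mutant in an `X`
resident population; this reading reproduces the stationary cooperation
levels that the acceptance pipeline checks.

**Embedded chain.** Off-diagonal entries are the rates scaled by the uniform
mutant-appearance probability `1/(2M)` (strategy and repertoire of a mutant
are independent and uniform); each rate is at most ½, so diagonals
`1 − Σ_{j≠i} A_ij` are always non-negative. Because the stationary
distribution is invariant to any uniform rescaling of the off-diagonal rates
(a property the tests enforce at 10⁻¹⁰), the omitted mutation rate and the
`1/(2M)` factor never influence the reported quantities. The stationary
vector is computed with a dense eigen-decomposition of `Aᵀ` (the chain is
100×100 at the defaults, so sparse machinery would be overhead): the
eigenvalue nearest 1 must be unique within 10⁻⁹, the real part is taken, the
sign fixed by the vector sum, entries clipped at zero, and the residual
`‖πA − π‖∞` must be below 10⁻¹⁰ or a degenerate-chain error is raised.
`K_C*`/`K_D*` are the repertoires carrying maximal stationary mass within
each strategy class; ties within 10⁻¹² resolve to the smallest repertoire.

**β peak.** `find_beta_peak` scans a 40-point grid over the requested range
(default `(0, 0.2]`), then refines the bracketed maximizer with a bounded
scalar minimization (`xatol = 10⁻⁶`) and reports 4 decimal places. A grid
argmax on the range boundary is flagged `interior=False` (no interior peak)
and returned unrefined. The cooperation-level landscape around its maximum is
extremely flat — level changes of order 10⁻³ across a ±0.01 window of `β` —
so comparisons of the *location* of the peak are far more delicate than
comparisons of the level itself.

## Agent-based simulator

The simulator is the same process with nothing marginalized out: payoffs are
recomputed from scratch every step via per-phenotype count arrays (an `O(N+M)`
pass; at `N = 20` incremental caching would buy nothing and cost complexity),
parent selection exponentiates shifted payoffs so strong selection cannot
overflow, and the hot loops are numba-compiled. All randomness flows from the
run's single seed; identical seeds give byte-identical trajectories. Time is
reported in birth-death update steps (one generation = `N` steps, a
documentation convention only). Occupancy histograms assign each recording
snapshot fractionally: every agent contributes `1/N` to its strain's bin, so
mixed snapshots are split by strain counts.

What the simulator emulates is exactly the model above — it is the model, not
a data generator fitted to anything external. What it does *not* emulate is
any feature of real biological populations beyond the model's assumptions:
constant population size, complete mixing, pairwise-additive payoffs, no
within-lifetime phenotype switching, no environmental fluctuation. Agreement
between simulator and analytics therefore validates the mathematics and the
implementation, not the model's fidelity to any organism.

Replicated-invasion experiments (`fixation_frequency`) seed one mutant into
`N−1` residents with `μ = 0` and run to absorption; with `δ` pinned they
reproduce the exact fixation probabilities within Monte-Carlo error (checked
at 3 standard errors with 2×10⁴ replicates), and with phenotypes drawn from
the nested universe they bracket the strain-replacement rates.

## Design choices on genuinely open points

- **Clonal expression inheritance.** Non-mutant offspring inherit the
  parental expressed phenotype verbatim. The fixed-`δ` fixation analysis
  presumes exactly this; re-randomizing expression at birth would be a
  different model. The simulator follows the same convention.
- **Death before insertion.** The dying individual is drawn from the `N`
  present before the offspring is inserted — the standard Moran convention,
  and the one whose `T_{i,i±1}` structure the fixation formulas encode.
- **Macro-state dominance.** A strategy class "holds" the population when it
  reaches a 0.95 fraction (exposed as a flag); coexistence requires both
  classes above 0.05. The diversity bands Low `(0,3]`, Middle `(3,38]`,
  High `(38,50]` are right-closed. Persistence/transition probabilities are
  reported as empirical frequencies *per lag of one recording interval*;
  absolute per-step persistence values are not asserted anywhere because they
  depend on an arbitrary time-unit convention.

## Problem sizes used by the test suite

The analytic checks run at the full study conditions (`M = 50`, 100-state
chains). Stochastic cross-validation uses deliberately small instances chosen
for statistical power per CPU-second: fixation frequencies at `N = 10` with
2×10⁴ replicates, Monte-Carlo rate brackets at `N = 4, M = 2` with 2×10⁵
replicates, and long-run occupancy at `N = 10, M = 3` with 10⁷–2×10⁷ updates.

## Known limitations

- **Founder-label bias of the strain-level chain.** The strain-replacement
  rate assumes the residents' expressed label is uniform over their
  repertoire at each mutation event. In the true process the label was fixed
  when the resident strain's founder fixated, and founders that matched their
  predecessors fixate at different rates than those that did not — so the
  resident label is *not* uniform conditional on residency. A label-refined
  embedded chain over `(strain, expressed label)` states (built as an
  independent oracle in the test suite) captures this exactly, and the
  simulator's long-run occupancy matches it within total-variation 0.05 at
  `N = 10, M = 3`. At small `M` the discrepancy between the refined and the
  strain-level chain is material (the bias does not vanish as `μ → 0`);
  at the standard conditions (`M = 50, N = 20`) the label bias spreads over
  many labels and the strain-level chain is an excellent approximation.
- **Small-mutation approximation.** The embedded chain assumes at most two
  strains ever coexist. Finite `μ` introduces additional deviations beyond
  the label bias; empirical agreement is documented at `μ` of order 10⁻³
  only.
- The continuous strategy square `[p, q] ∈ [0,1]²`, structured populations,
  multi-player interactions, and directed (non-uniform) phenotype switching
  are out of scope.
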