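# Methods

## The stochastic model

The package models the *active* hematopoietic stem cell compartment as a
well-mixed pool of N cells undergoing discrete birth-death events.  At each
event one cell is selected for division (uniformly under neutrality), the
daughter of a normal parent acquires a PIG-A mutation with probability μ,
and one of the N+1 cells is then selected uniformly for differentiation and
leaves the pool.  With no fitness differences this is a neutral Moran
process with one-way mutation (no back-mutation).  Its master equation is
evolved exactly as a linear recursion on the probability vector over mutant
counts; nothing is sampled.

Biological time enters through the replication rate: active HSC replicate
about once per cell per year, so N events correspond to one year at pool
size N.  All horizons in the package are expressed this way (an "adult
year" is 400 events).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| μ (`mu`) | 5×10⁻⁷ | per replication | PIG-A loss-of-function rate of normal cells |
| `n_birth` | 20 | cells | active pool size at birth |
| `n_adult` | 400 | cells | active pool size at and after maturity |
| `maturity_age` | 18 | years | age at which the pool reaches `n_adult` |
| `growth_interval_days` | 14 | days | grid on which growth divisions are inserted |
| clinical threshold | 0.2 | fraction of pool | diagnosis when m ≥ ceil(0.2·N) |
| `r_pig_a`, `r_healthy` | 1, 1 | — | optional relative fitness (division pick) |

The replication rate is not a free knob: it is fixed at one per cell per
year by the event clock.

## Ontogenic growth

The pool grows 20 → 400 between birth and maturity.  The growth curve's
published derivation scales the active pool with body mass, so the default
curve form (`mass_table`) maps the fraction of body mass gained by age a
(from a standard mass-for-age reference table, age axis rescaled to the
configured maturity age) onto the fraction of pool cells gained, rounded to
integers and forced monotone.  A logistic-in-age form and a user-supplied
`(age, pool size)` table are available as alternatives; endpoint behaviour
(20 at birth, 400 from maturity on) is identical across forms, but
childhood quantities — in particular the cumulative replication count by
age 20 and hence the early mutation-acquisition probability — are
noticeably steeper under the logistic form, which is why the
mass-proportional curve is the default.

Growth is implemented as division-only events (a division with no
subsequent differentiation, extending the state space by one) inserted at
the end of two-week intervals so the pool tracks the curve; within each
interval, N/26 birth-death events are scheduled with the fractional
remainder carried in an exact integer accumulator, so every whole adult
year contains exactly 400 birth-death events and the total number of
growth divisions from birth to maturity is exactly 380.  Event order
within an interval (birth-death first, then growth divisions) is an
arbitrary but fixed convention.  Ages are snapped to the two-week grid.

## Transition operators

For a source state with k mutants the birth-death operator has three
nonzero entries (down / stay / up), built from the division pick, the
mutation branch and the differentiation pick.  In the neutral μ = 0 case
the closed symmetric form (Nk − k²)/(N(N+1)) is used directly for the up
and down entries, so the up/down symmetry of the mutation-free walk holds
to the last bit.  Columns sum to one to ≤10⁻¹²; probability mass over a
100-year evolution is conserved to ≤10⁻¹⁰ and is monitored, never
renormalized.  Entries more negative than −10⁻¹⁴ raise; smaller negative
round-off is clamped to zero with a logged warning.

With selection, the division pick uses r·m/(r·m + r_h·(N−m)).  The
differentiation pick stays uniform by default — the fitness factors govern
who replicates, not who differentiates — with an opt-in
`weighted_differentiation` switch that weights both picks, since either
reading of a fitness-weighted update is defensible.  Equal fitness factors
short-circuit to the neutral expressions, making the reduction exact
rather than approximate.

## The two-clone history chain

States are (i, m1, m2): i counts mutation events ever (0, 1, 2), m1 is the
first-arisen clone's current size, m2 the second's.  The state count is
1 + (N+1) + (N+1)(N+2)/2 (81,003 at N = 400).  Transitions within a
history mirror the single-clone operator applied to whichever of the three
subpopulations divides and differentiates; a mutating normal division
advances the history and seeds the new clone at size 1 *before* the
differentiation pick, so the seeded clone can be removed immediately —
"arose then died" is representable, and the tensor stays nearest-neighbour.
Growth divisions can also advance the history.  In history 2 the mutation
channel is off; consequently the probability of "3 or more clones" is not
computed, and P(i = 2) is an upper bound for it.  The truncation error of
stopping at two histories is of order P(≥3 mutation events) ≈ (μ·R)³/6
with R the lifetime replication count (~3×10⁻⁵ relative at default μ);
this is tested tightly at inflated μ against the single-clone chain.

Extinct-clone bookkeeping: a state contributes its arisen-clone count
(1 in history 1, 2 in history 2) to the denominator and its zero-size
arisen clones to the numerator.  The headline extinct fraction is
evaluated at age 100; a census-weighted variant can be formed from the
per-year summary table.

## Post-diagnosis statistics

Post-diagnosis analyses evolve the adult single-clone chain from a point
mass at ceil(f·N) for whole adult years, keeping μ at its default (its
effect over decades is negligible next to drift; a μ = 0 mode supports the
exact martingale checks).  The clone-growth query treats "≥5% increase per
year" as ≥5 percentage points of the pool, matching how clinical series
report clone percentages; a `relative` flag gives the other reading.  The
closed-form existence check uses the negative-binomial/binomial-tail
identity P(≥k mutations in x replications) with per-trial probability μ
(ignoring the O(m/N) depletion of normal cells, consistent with the
chain's i = 0 exit rate).

## Demography

Chain output is folded with an age pyramid over ages 1–100 (integer years,
chain sampled at year boundaries).  Prevalence uses the *current-state*
probability (the probability of being in a clinical state at age y), not
the ever-diagnosed first-passage probability; both are exposed, and
first-passage drives the age-at-diagnosis distribution.  Mean clone sizes
are reported as fractions of the pool so that childhood ages (smaller
pools) are commensurable with adult ages.

The repository does not bundle census data.  It ships (a) a parametric
plateau-and-decline synthetic pyramid generator for tests, and (b) a
synthetic reconstruction of the 2010 US single-year-of-age distribution
built by spreading published five-year-bin totals uniformly within bins
(linear decline within 85+), in
`src/pnhdrift/data/us_age_pyramid_2010_synthetic.csv`.  The reconstruction
matches the real table's coarse shape but not its single-year detail; the
folded quantities reported here (prevalence ≈ 1.6×10⁻⁵, biclonal
≈ 1.3×10⁻⁸, mean clinical clone size ≈ 31%, mean diagnosis age ≈ 48 y) are
insensitive to within-bin detail at the percent level.  A user with the
actual census table can pass it as an `age,count` CSV.

## Verification strategy

Two oracles are independent of the operator code: an exhaustive path
enumerator (every division / mutation / differentiation choice at the
level of individual cells, exact rational or float sums, pools ≤ 6 and ≤ 5
steps) and a vectorized Monte-Carlo agent simulator.  Chain-vs-simulation
checks run at inflated μ (10⁻³–10⁻²) and reduced pools so that mutation
events are observable with 10⁴–10⁵ replicates; default-μ behaviour is
validated by the exact chain and the closed forms, not by sampling.  The
simulator uses one seeded numpy generator with a fixed number of draws per
event across all replicates, so a given (seed, n_reps) reproduces the
ensemble bit-for-bit.

Classical invariants are asserted directly: neutral fixation probability
m/N (via linear solve on the operator, to 10⁻⁸), exact martingale of the
mean at μ = 0, up/down symmetry, column stochasticity, mass conservation,
nested-event monotonicities, and the right skew and variance growth of
post-diagnosis size distributions.

What passing tests do and do not show: the synthetic generators reproduce
the *model's* study conditions (pool sizes, rates, age structure), not
real hematopoiesis — the model has a single well-mixed active compartment,
no progenitor contribution, no attrition of the pool in old age, no
mortality differences by clone status, and a sharp 20% diagnosis rule, so
agreement with the package's expected values is a statement about the
neutral-drift model, not about any patient cohort.

## Known limitations

- The published ontogenic growth curve is not reproduced exactly; the
  mass-proportional default is a reconstruction of its substance.
  Childhood-age quantities carry this uncertainty (adult-age quantities
  are insensitive).
- The extinct-clone fraction at age 100 computes to ~95% (census-weighted
  ~90%), higher than the ~83% sometimes quoted for this model class; see
  the verification notes in the test suite — the value follows from the
  ~2/t survival decay of a neutral size-1 clone and is robust to the
  evaluation scheme.
- The multi-clone chain is neutral-only; selection is implemented for the
  single-clone chain.
- Clone genotypes/phenotypes (PNH II vs III) are not tracked; "two clones"
  means two independent stem-cell mutation events.
- Problem sizes used by the shipped analyses: full 100-year two-clone
  evolution at N = 400 (81,003 states, ~40,000 events) completes in well
  under a minute; oracle comparisons use pools of 10–50 cells.
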