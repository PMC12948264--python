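# Methods

This note documents the models, algorithms and numerical conventions
implemented in `pocrmkit`, the choices made where the design was genuinely
open, and what the simulation results do and do not establish.

## Dominance posets and exact counting

A combination is a tuple of 1-based dose-level indices, one per agent;
`a ≤ b` iff every coordinate of `a` is at most the corresponding coordinate
of `b`.  Grids may be restricted to an arbitrary subset of combinations
(the motivating trial studies 12 of the 24 cells of its 3×4×2 grid); the
subset inherits the order.  Coordinates carry the only semantics ("larger
index = higher dose"); milligram doses are metadata.

Linear extensions are enumerated by lexicographic depth-first search over
the minimal available elements, elements ordered by coordinate tuple.  This
fixes a deterministic, reproducible index for every ordering.  The index
convention is this package's own; published ordering numbers from other
software will not line up with ours, which is why membership operations take
explicit ordering sequences, never indices.

Counting does not enumerate.  The number of linear extensions equals the
number of maximal chains of the lattice of order ideals, computed by exact
integer DP: `f(∅) = 1`, `f(I) = Σ f(I \ {x})` over elements `x` maximal in
the ideal `I`.  Ideal lattices stay small (a few thousand states) for grids
whose extension counts are astronomically large, which is the entire point.
A resource guard (default 5·10⁶ ideals, configurable) fails loudly rather
than exhausting memory.  On the 2×2×3 grid the DP gives 2452; where an
alternative figure of 2163 circulates for that grid, the DP value is the
one this package reports (it also matches full enumeration).

## Order-scenarios and correct ordering groups

For a monotone-consistent toxicity scenario with a single MTC at rank ν,
the below-MTC set B (combinations with DLT probability strictly below the
MTC's) is automatically an order ideal containing the MTC's strict down-set
and avoiding its strict up-set.  Conversely every such ideal is realisable
by a monotone scenario, so the order-scenarios of a poset are exactly the
pairs (m, strict-down(m) ∪ J) with J an ideal of the subposet incomparable
to m.  Enumeration and counting follow this characterisation; on the
motivating poset it yields 47 order-scenarios.  Note the characterisation
is derived for *strict* below-sets: ties below the MTC land in B only when
strictly below, and a non-MTC combination sharing the MTC's probability is
rejected as an error because B would be undefined.

The correct ordering group of an order-scenario factorises: any extension
of B, then the MTC, then any extension of the rest.  Group sizes are
computed by that product of sub-poset extension counts; the constructive
version (seeded random extension of B + MTC + seeded random extension of
the rest) always produces a group member because B is a sandwiched ideal.

Relabeling ties: combinations with equal probability are ranked by the
partial order first (a dominated element gets the lower rank), then
lexicographically.  Ranks among tied non-MTC combinations never affect a
correct-group computation, which depends only on (MTC, B).

## Adding–Refining and minimal consistent subsets

*Adding* traverses the enumerated order-scenarios (exhaustive up to a cap
of 10 000, beyond that a seeded random sample drawn by ideal up-growth —
non-uniform, which is fine because only coverage matters) and appends a
constructed correct ordering whenever the current list covers none of a
scenario's group.  *Refining* performs the randomized subset search:
uniformly random subsets of size S (always containing any user-fixed
orderings), 10⁵ attempts per size by default, growing S on failure.  The
candidate list for Refining is a parameter; by default it is the Adding
output.  Because a failed randomized search certifies nothing, an exact
branch-and-bound set cover (`exact_min_cover`) is provided; it prunes with
a greedy disjoint-row lower bound, which is sharp here because scenario
rows sharing an MTC rank have pairwise disjoint correct groups.  On the
motivating 148×47 instance it certifies a minimum of 8 orderings in well
under a second; the randomized Refining typically lands on 8–10.

n.consis priors are proportional to the per-ordering count of covered
scenarios.  A zero count would violate the requirement that no included
ordering has zero prior, so zero counts are floored at 1 (with a warning)
before normalisation.

## The two-stage likelihood-based POCRM

Stage 1 assigns cohorts of one patient along a pre-specified escalation
path until the first DLT (parking at the final path element if the path is
exhausted; a trial with no DLT at all recommends the last administered
combination, a convention this package fixes since the procedure itself is
silent there).  Stage 2, after each cohort: fit the CRM under every
candidate ordering, select the ordering maximising prior × likelihood, and
assign the next cohort to the combination whose estimated DLT probability
is closest to the TTL.  The final recommendation repeats that computation
on the complete data after the last patient.

Working model: the one-parameter power ("empiric") model
p = α^exp(θ) — the standard POCRM working model; the skeleton value α_l
attaches to ordering position l.  Two estimation modes exist because the
literature is ambiguous between a likelihood-based and a fully Bayesian
reading of ordering selection:

* `"ml"` (default): θ̂ maximises the Bernoulli log-likelihood over bounds
  [−10, 10]; the ordering score is the prior times the *maximized*
  likelihood; estimates are plug-in.
* `"bayes"`: zero-mean normal prior on θ with s.d. 1.34, 25-node
  Gauss–Hermite quadrature; the score uses the *integrated* likelihood and
  estimates are posterior means of the model probabilities.

This is a documented semantic fork; neither mode is privileged beyond the
`"ml"` default, and the two agree in ranking whenever the likelihood is
sharply peaked.

Numerics.  The log-likelihood is concave in u = exp(θ) (its u-score is
monotone decreasing), so the MLE is found by 25 safeguarded bisection steps
on the score's sign, vectorized over (simulated trial, ordering); θ is
resolved to ~10⁻⁶.  Combinations never treated contribute exactly zero to
score and likelihood, so no masking is needed.  Homogeneous all-non-DLT
data clamp θ̂ to the upper bound (all estimates ≈ 0, so the design keeps
escalating along the selected ordering — benign); homogeneous all-DLT data
trigger a safety override that recommends the least toxic combination of
the selected ordering instead of trusting a clamped fit.  Ties: ordering
selection takes the lowest index; recommendation resolves toward the less
toxic combination (smaller estimate, then earlier ordering position).
There is no dose-skipping restriction: assignment is purely model-based.
Stage-2 cohort size defaults to 1 (sequential enrolment); it is
configurable, and operating characteristics shift by a small amount when it
is raised.

## Simulation engine and problem sizes

Trials are simulated in a single vectorized pass across replicates (one
uniform draw per patient per trial from one seeded generator), making 10⁴
replicates affordable; single-trial runs are the n=1 special case and are
bit-reproducible given the seed.  The benchmark configuration bundled with
the package is the motivating trial's: TTL 0.25, skeleton
(0.0003, 0.02, 0.04, 0.08, 0.19, 0.25, 0.28, 0.31, 0.38, 0.44, 0.50, 0.56),
the 12-step stage-1 path from the least to the most toxic combination, and
N = 60 patients.  The acceptance script and test suite estimate PCS with
2000 replicates (binomial SE ≈ 0.7 percentage points at PCS ≈ 88%), and the
large-sample consistency checks use N = 1000 with 500 replicates; these
sizes are the package's chosen benchmark scale, an order of magnitude below
exhaustive study sizes but comfortably beyond Monte-Carlo noise for the
comparisons made.

## The synthetic scenario generator

`generate_scenario` emulates monotone combination-toxicity surfaces with a
prescribed order-scenario: the MTC sits exactly at the TTL, below-set
members receive distinct probabilities in (0, TTL − gap) increasing along a
random linear extension of B, the remainder distinct probabilities in
(TTL + gap, 1); the default gap is 0.05.  The construction guarantees
monotone consistency and an exact round trip back to the target
order-scenario.  What it does *not* emulate: plateaus (ties), probabilities
arbitrarily close to the TTL, non-monotone drug–drug antagonism, or any
pharmacological structure linking the agents — passing tests built on it
demonstrate the combinatorial machinery and the design's behaviour under
clean monotone scenarios, not robustness to messy real dose-toxicity
surfaces.  The bundled 12 benchmark scenarios are hand-specified, not
generated.

## Known limitations

* Uniform sampling of linear extensions is out of scope; the seeded
  randomizers cover their targets but are not uniform, and randomized
  Refining output sizes are run-dependent by design.
* No safety stopping rules, overdose control, or committee-overrule
  workflows; binary DLT outcomes only.
* Published two-dimensional order-scenario counts based on other
  conventions differ from the below-set enumeration implemented here for
  some grids (e.g. 2×2); this package reports the below-set counts, which
  are the ones the consistency theory characterises.
* The poset resource guard makes very large grids fail fast rather than
  degrade; counting beyond ~5·10⁶ ideals requires raising the guard and a
  machine to match.
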