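# pocrmkit

Ordering specification and trial simulation for the **partial order
continual reassessment method (POCRM)** in high-dimensional drug-combination
dose finding.

## The problem

Phase I combination trials seek the maximum tolerated dose combination
(MTC): the combination whose dose-limiting toxicity (DLT) probability is
closest to a target toxicity level (TTL, typically 0.25).  Each single agent
is monotone in toxicity, so the combinations carry a componentwise dominance
*partial* order — `(2,3,1) ≤ (3,3,1)` is known, but `(2,4,1)` vs `(3,3,1)`
is not.  The POCRM handles this by carrying a set of candidate *complete
orderings* (linear extensions of the dominance poset), selecting among them
by prior-weighted likelihood, and running a one-parameter CRM under the
selected ordering:

> p(θ; α_l) = α_l^exp(θ)

where α is an increasing skeleton of guess probabilities attached to
ordering positions.  The catch: the number of linear extensions M\* explodes
combinatorially (already 24 024 for a 4×4 two-agent grid), so one must pick
a *small* set of orderings — and picking badly destroys the design.

The selection principle implemented here is **asymptotic consistency**.
For a toxicity scenario R with MTC rank ν and below-MTC set B (the
combinations strictly less toxic than the MTC), an ordering 𝒪 is in the
*correct ordering group* iff 𝒪[ν] is the MTC and 𝒪[1:ν−1] = B; including at
least one member is necessary and sufficient for the probability of correct
selection (PCS) to converge to 1.  The group depends only on the
*order-scenario* (MTC, B) — and B is always an order ideal sandwiched
between the MTC's strict down-set and the complement of its up-set, so all
order-scenarios are enumerable even when the orderings are not.  The
**Adding–Refining** algorithm exploits this: *Adding* walks the
order-scenarios and constructs a covering ordering for each uncovered one;
*Refining* prunes the result to a small consistent subset (with an exact
branch-and-bound set-cover as a certified counterpart).  The **n.consis
prior** weights each ordering by the number of scenarios whose correct
group contains it.

## What's in the package

| module | contents |
| --- | --- |
| `pocrmkit.poset` | dominance posets on dose grids; linear-extension enumeration and exact counting by DP over the order-ideal lattice; order ideals |
| `pocrmkit.scenarios` | toxicity scenarios, relabeling, MTC, order-scenarios, correct ordering groups, constructive correct orderings |
| `pocrmkit.selection` | coverage matrices, consistency checks, Adding–Refining, exact minimum covers, n.consis priors |
| `pocrmkit.design` | two-stage likelihood-based POCRM: power-model CRM fits (ML or Bayes), ordering selection, recommendation, vectorized trial engine |
| `pocrmkit.evaluation` | PCS estimation and curves, geometric-mean summaries, the 12 bundled benchmark scenarios, a synthetic monotone scenario generator |
| `pocrmkit.fileio` / `pocrmkit.cli` | CSV/JSON/YAML round-trips, run manifests, and the `pocrmkit` command line |

## Worked example

The motivating application is a three-drug pediatric oncology trial with 12
combinations of 3×4×2 dose levels (a strict subset of the full grid):

```python
import numpy as np
import pocrmkit as pk

poset = pk.motivating_poset()
print("M* =", pk.count_linear_extensions(poset))       # M* = 148
scenarios = pk.enumerate_order_scenarios(poset)
print("order-scenarios:", len(scenarios))              # order-scenarios: 47

# a benchmark scenario whose MTC (2,2,2) sits mid-grid at probability 0.25
r2 = pk.table3_scenarios()[1]
os2 = pk.order_scenario_of(r2, ttl=0.25)
print("MTC:", os2.mtc, " rank nu:", os2.nu)            # MTC: (2, 2, 2)  rank nu: 6
print("correct group size:", pk.correct_group_size(os2, poset))   # 16

# scenario-agnostic ordering specification without listing all 148 orderings
added = pk.adding_step(poset, rng_seed=1)
print("Adding step kept", len(added), "orderings")     # 11
refined = pk.refining_step(added, added.scenarios, rng_seed=1)
print("Refining step kept", len(refined), "orderings") # 10

# certified minimum over the full 148 x 47 coverage instance
from pocrmkit.selection import coverage_matrix, exact_min_cover
cov = coverage_matrix(pk.enumerate_linear_extensions(poset), scenarios)
print("certified minimum subset:", len(exact_min_cover(cov)))     # 8

# n.consis priors over the refined orderings, w.r.t. the 12 benchmark scenarios
os12 = [pk.order_scenario_of(s, 0.25) for s in pk.table3_scenarios()]
weights = pk.n_consis_prior(refined, os12)
print("n.consis priors:", np.round(weights.weights, 3))
# [0.094 0.113 0.094 0.075 0.094 0.075 0.132 0.113 0.113 0.094]

# operating characteristics of the two-stage POCRM at N = 60
config = pk.motivating_config(refined, n_max=60, priors=weights)
est = pk.estimate_pcs(r2, config, n_sims=1000, seed=1)
print(f"PCS under the mid-grid scenario, N=60: {est.pcs:.3f} (SE {est.se:.3f})")
# PCS under the mid-grid scenario, N=60: 0.339 (SE 0.015)
```

Reading the output: 148 complete orderings collapse to 47 order-scenarios;
a randomized Adding–Refining run keeps 10 consistent orderings while the
certified minimum is 8; and at a realistic sample size of 60 patients the
design finds the hardest (mid-grid) MTC in about a third of trials — small-N
PCS in the 30–50% range is the expected operating characteristic here, while
consistency guarantees convergence to 100% as N grows.

The same operations are available from the shell, e.g.

```sh
pocrmkit count --levels 2 2 3          # prints 2452
pocrmkit scenarios --grid table1       # prints 47
pocrmkit add-refine --grid table1 --seed 1 --out orderings.csv
```

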