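"""Toxicity scenarios, relabeling, order-scenarios and correct ordering groups.

A *toxicity scenario* assigns a DLT probability to every combination; the MTC
is the combination whose probability is closest to the target toxicity level
(TTL).  Relabeling sorts the combinations by probability; the MTC's rank nu
and the *below-MTC set* B (combinations strictly less toxic than the MTC)
together form the *order-scenario*.  An ordering belongs to the *correct
ordering group* of a scenario when the MTC sits at position nu and the first
nu-1 positions are exactly B — and inclusion of at least one such ordering is
necessary and sufficient for the POCRM to select the MTC with probability
tending to one as the sample size grows.

The key structural fact used throughout: B is always an order ideal wedged
between the strict down-set of the MTC and the complement of its up-set, so
admissible B's are exactly strict-down(mtc) united with an order ideal of the
subposet of elements incomparable to the MTC.  That makes the order-scenarios
enumerable even when the linear extensions are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .poset import (
    Combination,
    CombinationPoset,
    Ordering,
    _bits,
    _ideal_masks,
    count_linear_extensions,
    enumerate_linear_extensions,
    format_combination,
    random_linear_extension,
)


class MonotonicityError(ValueError):
    """A scenario violates dominance monotonicity of the DLT probabilities."""


class TieError(ValueError):
    """No single MTC / the MTC probability is shared by another combination."""


@dataclass(frozen=True)
class ToxicityScenario:
    """A scenario of true DLT probabilities on a combination poset."""

    poset: CombinationPoset
    probs: dict[Combination, float]
    name: str = ""

    def __post_init__(self) -> None:
        probs = {tuple(c): float(p) for c, p in self.probs.items()}
        object.__setattr__(self, "probs", probs)
        if set(probs) != set(self.poset.elements):
            raise ValueError("scenario domain must equal the poset's elements")
        for c, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} for {c} outside [0, 1]")
        for i, a in enumerate(self.poset.elements):
            for j, b in enumerate(self.poset.elements):
                if self.poset.leq[i, j] and probs[a] > probs[b]:
                    raise MonotonicityError(
                        f"prob({format_combination(a)})={probs[a]} exceeds "
                        f"prob({format_combination(b)})={probs[b]} although "
                        f"{format_combination(a)} <= {format_combination(b)}"
                    )

    def prob_array(self) -> np.ndarray:
        """Probabilities aligned with ``poset.elements``."""
        return np.array([self.probs[c] for c in self.poset.elements])

    def __getitem__(self, combo: Combination) -> float:
        return self.probs[tuple(combo)]


@dataclass(frozen=True)
class OrderScenario:
    """An (MTC, below-MTC set) pair; the MTC rank is ``nu = |B| + 1``."""

    mtc: Combination
    below: frozenset[Combination]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mtc", tuple(self.mtc))
        object.__setattr__(
            self, "below", frozenset(tuple(c) for c in self.below)
        )
        if self.mtc in self.below:
            raise ValueError("the MTC cannot be in its own below-MTC set")

    @property
    def nu(self) -> int:
        return len(self.below) + 1

    def validate(self, poset: CombinationPoset) -> None:
        """Check the ideal sandwich structure against ``poset``."""
        poset.index(self.mtc)
        for c in self.below:
            poset.index(c)
        down = poset.down_set(self.mtc, strict=True)
        up = poset.up_set(self.mtc, strict=True)
        if not down <= self.below:
            raise ValueError("below set must contain the MTC's strict down-set")
        if self.below & up:
            raise ValueError("below set intersects the MTC's strict up-set")
        for c in self.below:
            if not poset.down_set(c, strict=True) <= self.below:
                raise ValueError("below set is not an order ideal")


def find_mtc(scenario: ToxicityScenario, ttl: float) -> Combination:
    """The unique combination with DLT probability closest to the TTL.

    Raises :class:`TieError` when two combinations are equally close.
    """
    dist = {c: abs(p - ttl) for c, p in scenario.probs.items()}
    best = min(dist.values())
    hits = [c for c, d in dist.items() if math.isclose(d, best, abs_tol=1e-12)]
    if len(hits) > 1:
        raise TieError(
            f"no single MTC: {[format_combination(c) for c in sorted(hits)]} "
            f"are equally close to TTL {ttl}"
        )
    return hits[0]


def relabel(scenario: ToxicityScenario) -> dict[Combination, int]:
    """Rank the combinations 1..L by increasing DLT probability.

    Ties are broken first by the dominance order (a dominated element gets
    the lower rank, so the ranking is always a linear extension restricted to
    each tie group), then lexicographically by coordinates.
    """
    poset = scenario.poset
    groups: dict[float, list[Combination]] = {}
    for c in poset.elements:
        groups.setdefault(scenario.probs[c], []).append(c)
    ranks: dict[Combination, int] = {}
    next_rank = 1
    for p in sorted(groups):
        tied = groups[p]
        # lexicographic-first topological order within the tie group
        sub = poset.restrict(tied)
        for c in enumerate_linear_extensions(sub, cap=1)[0]:
            ranks[c] = next_rank
            next_rank += 1
    return ranks


def order_scenario_of(scenario: ToxicityScenario, ttl: float) -> OrderScenario:
    """Reduce a toxicity scenario to its order-scenario at the given TTL."""
    mtc = find_mtc(scenario, ttl)
    p_mtc = scenario.probs[mtc]
    for c, p in scenario.probs.items():
        if c != mtc and p == p_mtc:
            raise TieError(
                f"{format_combination(c)} shares the MTC probability {p_mtc}; "
                "the below-MTC set is undefined"
            )
    below = frozenset(c for c, p in scenario.probs.items() if p < p_mtc)
    return OrderScenario(mtc=mtc, below=below)


def in_correct_group(ordering: Ordering, os: OrderScenario) -> bool:
    """Membership in the correct ordering group of the order-scenario.

    True iff position ``nu`` holds the MTC and the first ``nu - 1``
    positions are exactly the below-MTC set.
    """
    nu = os.nu
    if len(ordering) < nu:
        raise ValueError("ordering shorter than the MTC rank")
    return ordering.at(nu) == os.mtc and set(ordering.sequence[: nu - 1]) == os.below


def correct_group_size(os: OrderScenario, poset: CombinationPoset) -> int:
    """Exact size of the correct ordering group.

    By the sandwich structure the group factorises: any linear extension of
    the induced poset on B, then the MTC, then any linear extension of the
    induced poset on the remaining combinations.
    """
    os.validate(poset)
    rest = [e for e in poset.elements if e != os.mtc and e not in os.below]
    return count_linear_extensions(poset.restrict(os.below)) * count_linear_extensions(
        poset.restrict(rest)
    )


def correct_group(os: OrderScenario, poset: CombinationPoset) -> list[Ordering]:
    """All orderings in the correct group (list mode of the product formula)."""
    os.validate(poset)
    rest = [e for e in poset.elements if e != os.mtc and e not in os.below]
    lows = enumerate_linear_extensions(poset.restrict(os.below))
    highs = enumerate_linear_extensions(poset.restrict(rest))
    out = []
    for lo in lows:
        for hi in highs:
            out.append(Ordering(lo.sequence + (os.mtc,) + hi.sequence))
    return out


class OrderScenarioList(list):
    """List of order-scenarios; ``exhaustive`` is False for a sampled subset."""

    exhaustive: bool = True


def count_order_scenarios(poset: CombinationPoset) -> int:
    """Number of order-scenarios: sum over candidate MTCs of the number of
    order ideals of the subposet incomparable to the MTC."""
    from .poset import incomparable_subposet

    return sum(
        len(_ideal_masks(incomparable_subposet(poset, m))) for m in poset.elements
    )


def enumerate_order_scenarios(
    poset: CombinationPoset,
    mtc_list: Optional[Iterable[Combination]] = None,
    cap: int = 10_000,
    rng_seed: int = 0,
) -> OrderScenarioList:
    """All order-scenarios, or a seeded random sample when they exceed ``cap``.

    For each candidate MTC ``m`` the admissible below-MTC sets are
    ``strict-down(m)`` united with each order ideal of the subposet
    incomparable to ``m``.  When the total count exceeds ``cap``, ``cap``
    scenarios are drawn by seeded random up-growth of ideals (non-uniform;
    the consumer, the Adding step, only needs coverage).
    """
    from .poset import incomparable_subposet

    mtcs = list(mtc_list) if mtc_list is not None else list(poset.elements)
    for m in mtcs:
        poset.index(m)
    incs = {m: incomparable_subposet(poset, m) for m in mtcs}
    totals = {m: len(_ideal_masks(incs[m])) for m in mtcs}
    out = OrderScenarioList()
    if sum(totals.values()) <= cap:
        for m in mtcs:
            down = poset.down_set(m, strict=True)
            for mask in _ideal_masks(incs[m]):
                out.append(OrderScenario(mtc=m, below=down | incs[m].mask_to_set(mask)))
        return out
    rng = np.random.default_rng(rng_seed)
    seen: set[OrderScenario] = set()
    while len(out) < cap:
        m = mtcs[int(rng.integers(len(mtcs)))]
        sub = incs[m]
        mask = _random_ideal_mask(sub, rng)
        os = OrderScenario(mtc=m, below=poset.down_set(m, strict=True) | sub.mask_to_set(mask))
        if os not in seen:
            seen.add(os)
            out.append(os)
    out.exhaustive = False
    return out


def _random_ideal_mask(poset: CombinationPoset, rng: np.random.Generator) -> int:
    """Seeded random ideal by up-growth: repeatedly either stop or add a
    uniformly chosen addable element.  Covers every ideal with positive
    probability, but not uniformly."""
    n = len(poset)
    down = poset._down_masks
    mask = 0
    while True:
        addable = [
            i for i in range(n) if not (mask >> i) & 1 and not (down[i] & ~mask)
        ]
        if not addable or rng.random() < 1.0 / (len(addable) + 1):
            return mask
        mask |= 1 << addable[int(rng.integers(len(addable)))]


def construct_correct_ordering(
    os: OrderScenario, poset: CombinationPoset, rng_seed: int | np.random.Generator = 0
) -> Ordering:
    """A seeded random member of the correct group (the constructive recipe:
    random extension of B, then the MTC, then a random extension of the rest).

    A valid completion always exists because B is an ideal sandwiched between
    the MTC's strict down-set and the complement of its up-set.
    """
    os.validate(poset)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    rest = [e for e in poset.elements if e != os.mtc and e not in os.below]
    lo = random_linear_extension(poset.restrict(os.below), rng) if os.below else Ordering(())
    hi = random_linear_extension(poset.restrict(rest), rng) if rest else Ordering(())
    return Ordering(lo.sequence + (os.mtc,) + hi.sequence)
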