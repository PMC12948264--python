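"""Ordering specification: the Adding-Refining algorithm and consistency checks.

A candidate set of orderings is *consistent* when, for every possible
order-scenario, at least one member lies in that scenario's correct ordering
group.  The coverage matrix (scenarios x orderings) makes this a set-cover
problem: each scenario row must contain at least one selected column.

The Adding step walks the enumerated order-scenarios and, whenever the
current list covers none of a scenario's correct group, appends a randomly
constructed member of that group.  The Refining step then searches for a
small consistent subset by repeated random subset draws, growing the subset
size when a budget of attempts is exhausted.  ``exact_min_cover`` is the
deterministic branch-and-bound counterpart that certifies minimality, which
a failed randomized search cannot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .poset import CombinationPoset, Ordering, is_linear_extension
from .scenarios import (
    OrderScenario,
    construct_correct_ordering,
    enumerate_order_scenarios,
    in_correct_group,
)


class InconsistentSetError(ValueError):
    """The candidate orderings do not cover every order-scenario."""


class NoConsistentSubsetError(RuntimeError):
    """The randomized search exhausted its budget without finding a
    consistent subset of the requested size."""


@dataclass(frozen=True)
class CoverageMatrix:
    """Correct-group membership table: rows are order-scenarios, columns
    orderings; cell (r, c) is True when ordering c lies in the correct
    group of scenario r."""

    scenarios: tuple[OrderScenario, ...]
    orderings: tuple[Ordering, ...]
    cells: np.ndarray  # bool, shape (len(scenarios), len(orderings))

    def covered_rows(self, columns: Sequence[int]) -> np.ndarray:
        if len(columns) == 0:
            return np.zeros(len(self.scenarios), dtype=bool)
        return self.cells[:, list(columns)].any(axis=1)

    def is_consistent(self, columns: Sequence[int]) -> bool:
        return bool(self.covered_rows(columns).all())

    def n_consis(self) -> np.ndarray:
        """Per-ordering count of scenarios whose correct group contains it."""
        return self.cells.sum(axis=0)


@dataclass(frozen=True)
class PriorWeights:
    """Prior probabilities over a list of orderings; nonnegative, sum to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if (w < 0).any():
            raise ValueError("prior weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("prior weights must sum to 1")

    @classmethod
    def equal(cls, n: int) -> "PriorWeights":
        return cls(np.full(n, 1.0 / n))

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, m: int) -> float:
        return float(self.weights[m])


def coverage_matrix(
    orderings: Sequence[Ordering], scenarios: Sequence[OrderScenario]
) -> CoverageMatrix:
    """Full correct-group membership table."""
    cells = np.zeros((len(scenarios), len(orderings)), dtype=bool)
    for r, os in enumerate(scenarios):
        nu = os.nu
        for c, o in enumerate(orderings):
            cells[r, c] = o.at(nu) == os.mtc and set(o.sequence[: nu - 1]) == os.below
    return CoverageMatrix(tuple(scenarios), tuple(orderings), cells)


def is_consistent_set(
    orderings: Sequence[Ordering], scenarios: Sequence[OrderScenario]
) -> bool:
    """True iff every scenario's correct group contains >= 1 of the orderings.

    Vacuously true for an empty scenario list.
    """
    return all(any(in_correct_group(o, os) for o in orderings) for os in scenarios)


class AddingResult(list):
    """Orderings produced by the Adding step; ``scenarios`` holds the
    order-scenarios that were traversed (the Adding step lists them anyway,
    and the Refining step needs them)."""

    scenarios: tuple[OrderScenario, ...] = ()


def adding_step(
    poset: CombinationPoset,
    initial_orderings: Sequence[Ordering] = (),
    fixed_orderings: Sequence[Ordering] = (),
    cap: int = 10_000,
    rng_seed: int = 0,
) -> AddingResult:
    """Grow a covering set of orderings scenario-by-scenario.

    Traverses the enumerated order-scenarios (exhaustive up to ``cap``, else
    a seeded sample); whenever no current ordering lies in a scenario's
    correct group, a randomly constructed member is appended.  The output
    contains the fixed and initial orderings and covers every traversed
    scenario.
    """
    for o in list(initial_orderings) + list(fixed_orderings):
        if not is_linear_extension(o, poset):
            raise ValueError("initial/fixed orderings must be linear extensions")
    scenarios = enumerate_order_scenarios(poset, cap=cap, rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    current: list[Ordering] = list(fixed_orderings) + [
        o for o in initial_orderings if o not in fixed_orderings
    ]
    for os in scenarios:
        if not any(in_correct_group(o, os) for o in current):
            current.append(construct_correct_ordering(os, poset, rng))
    out = AddingResult(current)
    out.scenarios = tuple(scenarios)
    return out


def refining_step(
    orderings: Sequence[Ordering],
    scenarios: Sequence[OrderScenario],
    attempts_per_size: int = 10**5,
    rng_seed: int = 0,
    fixed_orderings: Sequence[Ordering] = (),
) -> list[Ordering]:
    """Randomized search for a small consistent subset.

    Starting from the smallest admissible size S, draw uniformly-random
    subsets (always containing the fixed orderings) and return the first
    consistent one; if ``attempts_per_size`` draws fail, increase S by one.
    The input set must itself be consistent, so termination is guaranteed.
    """
    cov = coverage_matrix(orderings, scenarios)
    if not cov.is_consistent(range(len(orderings))):
        raise InconsistentSetError("the candidate ordering set is not consistent")
    fixed_idx = [list(orderings).index(o) for o in fixed_orderings]
    free_idx = np.array(
        [i for i in range(len(orderings)) if i not in set(fixed_idx)], dtype=int
    )
    rng = np.random.default_rng(rng_seed)
    base_covered = cov.covered_rows(fixed_idx)
    need = ~base_covered
    if not need.any():
        return [orderings[i] for i in fixed_idx]
    sub_cells = cov.cells[need][:, free_idx]  # rows still to cover x free cols
    for size in range(1, len(free_idx) + 1):
        found = _random_cover_search(sub_cells, size, attempts_per_size, rng)
        if found is not None:
            chosen = sorted(fixed_idx + [int(free_idx[j]) for j in found])
            return [orderings[i] for i in chosen]
    raise AssertionError("unreachable: full set is consistent")


def _random_cover_search(
    cells: np.ndarray, size: int, attempts: int, rng: np.random.Generator
) -> Optional[np.ndarray]:
    """Batched random subset draws; returns column indices of the first
    subset covering all rows, or None."""
    n_cols = cells.shape[1]
    if size > n_cols:
        return None
    batch = 2000
    done = 0
    while done < attempts:
        b = min(batch, attempts - done)
        # uniform subsets without replacement, drawn per attempt
        picks = np.argsort(rng.random((b, n_cols)), axis=1)[:, :size]
        hit = cells[:, picks].any(axis=2).all(axis=0)  # (rows, b, size) -> (b,)
        idx = np.flatnonzero(hit)
        if idx.size:
            return picks[idx[0]]
        done += b
    return None


def exact_min_cover(
    coverage: CoverageMatrix, fixed: Sequence[int] = ()
) -> list[Ordering]:
    """Provably minimum-cardinality consistent subset, by branch and bound.

    Branches on the uncovered row with the fewest covering columns; prunes
    with the incumbent size.  Deterministic given the input order.  Raises
    :class:`InconsistentSetError` if some row is uncoverable.
    """
    cells = coverage.cells
    n_rows, _ = cells.shape
    if n_rows and not cells.any(axis=1).all():
        raise InconsistentSetError("some order-scenario is covered by no ordering")
    fixed = list(fixed)
    best: list[Optional[list[int]]] = [None]

    # greedy incumbent for the initial bound
    def greedy() -> list[int]:
        chosen = list(fixed)
        covered = coverage.covered_rows(chosen)
        while not covered.all():
            gains = cells[~covered].sum(axis=0)
            c = int(np.argmax(gains))
            if gains[c] == 0:
                raise InconsistentSetError(
                    "some order-scenario is covered by no ordering"
                )
            chosen.append(c)
            covered = coverage.covered_rows(chosen)
        return chosen

    best[0] = greedy()

    def lower_bound(covered: np.ndarray) -> int:
        # rows whose candidate column sets are pairwise disjoint need one
        # distinct column each (rows sharing the MTC rank are automatically
        # disjoint, which makes this bound sharp in practice)
        acc = np.zeros(cells.shape[1], dtype=bool)
        lb = 0
        open_rows = np.flatnonzero(~covered)
        for r in open_rows[np.argsort(cells[open_rows].sum(axis=1), kind="stable")]:
            if not (cells[r] & acc).any():
                lb += 1
                acc |= cells[r]
        return lb

    def branch(chosen: list[int], covered: np.ndarray) -> None:
        assert best[0] is not None
        if covered.all():
            if len(chosen) < len(best[0]):
                best[0] = list(chosen)
            return
        if len(chosen) + lower_bound(covered) >= len(best[0]):
            return
        open_rows = np.flatnonzero(~covered)
        row = open_rows[int(np.argmin(cells[open_rows].sum(axis=1)))]
        cands = np.flatnonzero(cells[row])
        # explore high-coverage columns first
        cands = cands[np.argsort(-cells[:, cands][~covered].sum(axis=0), kind="stable")]
        for c in cands:
            branch(chosen + [int(c)], covered | cells[:, c])

    branch(fixed, coverage.covered_rows(fixed))
    assert best[0] is not None
    return [coverage.orderings[i] for i in sorted(best[0])]


def specify_order(
    scenarios: Sequence[OrderScenario],
    orderings: Sequence[Ordering],
    M: int,
    fixed: Sequence[Ordering] = (),
    rng_seed: int = 0,
    attempts: int = 10**5,
) -> list[Ordering]:
    """Pick M orderings (containing ``fixed``) consistent with ``scenarios``.

    Randomized search with the given attempt budget; raises
    :class:`NoConsistentSubsetError` when M is too small for the budget —
    with too few orderings there is no guarantee consistency is achievable.
    """
    if M < len(fixed):
        raise ValueError("M smaller than the number of fixed orderings")
    if M > len(orderings):
        raise ValueError("M exceeds the number of candidate orderings")
    cov = coverage_matrix(orderings, scenarios)
    fixed_idx = [list(orderings).index(o) for o in fixed]
    free_idx = np.array(
        [i for i in range(len(orderings)) if i not in set(fixed_idx)], dtype=int
    )
    need = ~cov.covered_rows(fixed_idx)
    size = M - len(fixed_idx)
    if not need.any() and size == 0:
        return [orderings[i] for i in fixed_idx]
    rng = np.random.default_rng(rng_seed)
    found = _random_cover_search(cov.cells[need][:, free_idx], size, attempts, rng)
    if found is None:
        raise NoConsistentSubsetError(
            f"no consistent subset of {M} orderings found in {attempts} attempts"
        )
    chosen = sorted(fixed_idx + [int(free_idx[j]) for j in found])
    return [orderings[i] for i in chosen]


def n_consis_prior(
    orderings: Sequence[Ordering], scenarios: Sequence[OrderScenario]
) -> PriorWeights:
    """Prior ordering weights proportional to the per-ordering count of
    scenarios under which it lies in the correct group.

    A zero count would give a zero prior, which breaks the consistency
    guarantee; zero counts are floored at 1 (with a warning) before
    normalisation.
    """
    counts = coverage_matrix(orderings, scenarios).n_consis().astype(float)
    return _weights_from_counts(counts)


def _weights_from_counts(counts: np.ndarray) -> PriorWeights:
    counts = np.asarray(counts, dtype=float).copy()
    if (counts == 0).any():
        warnings.warn(
            "some orderings lie in no correct group; their prior is floored at 1",
            stacklevel=2,
        )
        counts[counts == 0] = 1.0
    return PriorWeights(counts / counts.sum())
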