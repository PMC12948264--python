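"""Dose-combination grids as partially ordered sets.

A combination of several agents is written as a tuple of 1-based dose-level
indices, one per agent, e.g. ``(2, 3, 1)`` for the second level of drug A,
third of drug B, first of drug C.  Because each single agent is monotone in
toxicity, the combination space carries the componentwise dominance partial
order: ``a <= b`` iff every coordinate of ``a`` is at most the corresponding
coordinate of ``b``.  A *complete ordering* of the space is a linear extension
of this poset; the number of extensions grows combinatorially with the grid,
which is the core difficulty this package addresses.

Counting is done by dynamic programming over the lattice of order ideals
(down-sets): the number of linear extensions equals the number of maximal
chains from the empty ideal to the full ideal.  This avoids materialising
the extensions, whose count exceeds memory already for modest grids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

Combination = tuple[int, ...]

#: default ceiling on the number of order ideals visited before aborting
DEFAULT_MAX_IDEALS = 5_000_000


class PosetSizeError(RuntimeError):
    """The ideal lattice exceeded the configured resource guard."""


def dominates(a: Combination, b: Combination) -> bool:
    """True iff ``b`` componentwise dominates ``a`` (i.e. ``a <= b``).

    Reflexive: every combination dominates itself.  Raises ``ValueError``
    on arity mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"arity mismatch: {a} vs {b}")
    return all(x <= y for x, y in zip(a, b))


def format_combination(combo: Combination) -> str:
    """Render a combination as the dot-separated label ``"i.j.k"``."""
    return ".".join(str(i) for i in combo)


def parse_combination(label: str) -> Combination:
    """Parse a dot-separated label ``"i.j.k"`` back into a tuple."""
    try:
        return tuple(int(part) for part in label.strip().split("."))
    except ValueError as exc:
        raise ValueError(f"malformed combination label {label!r}") from exc


class CombinationPoset:
    """A set of combinations under the componentwise dominance order.

    Elements are stored in lexicographic order of their coordinate tuples;
    all matrix representations and enumeration orders refer to this fixed
    element order, which makes every derived quantity reproducible.
    """

    def __init__(
        self,
        levels_per_agent: Sequence[int],
        elements: Iterable[Combination],
    ) -> None:
        self.levels_per_agent: tuple[int, ...] = tuple(int(l) for l in levels_per_agent)
        if any(l < 1 for l in self.levels_per_agent):
            raise ValueError("every agent needs at least one dose level")
        elems = [tuple(int(i) for i in e) for e in elements]
        if len(set(elems)) != len(elems):
            raise ValueError("duplicate combinations in poset")
        for e in elems:
            if len(e) != self.n_agents:
                raise ValueError(f"combination {e} has wrong arity")
            if any(not (1 <= i <= lvl) for i, lvl in zip(e, self.levels_per_agent)):
                raise ValueError(f"combination {e} outside the grid")
        self.elements: tuple[Combination, ...] = tuple(sorted(elems))
        self._index = {e: i for i, e in enumerate(self.elements)}
        n = len(self.elements)
        leq = np.zeros((n, n), dtype=bool)
        for i, a in enumerate(self.elements):
            for j, b in enumerate(self.elements):
                leq[i, j] = dominates(a, b)
        self.leq = leq
        # bitmasks of strict down-/up-sets, used by the ideal-lattice walks
        strict = leq & ~np.eye(n, dtype=bool)
        self._down_masks = [_row_mask(strict[:, j]) for j in range(n)]
        self._up_masks = [_row_mask(strict[i, :]) for i in range(n)]

    # -- basic container protocol -------------------------------------------------

    @property
    def n_agents(self) -> int:
        return len(self.levels_per_agent)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[Combination]:
        return iter(self.elements)

    def __contains__(self, combo: object) -> bool:
        return combo in self._index

    def index(self, combo: Combination) -> int:
        try:
            return self._index[combo]
        except KeyError:
            raise KeyError(f"{combo} not an element of this poset") from None

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CombinationPoset)
            and self.levels_per_agent == other.levels_per_agent
            and self.elements == other.elements
        )

    def __repr__(self) -> str:
        grid = "x".join(str(l) for l in self.levels_per_agent)
        return f"CombinationPoset({grid} grid, {len(self)} elements)"

    # -- order queries ------------------------------------------------------------

    def le(self, a: Combination, b: Combination) -> bool:
        """``a <= b`` in the dominance order."""
        return bool(self.leq[self.index(a), self.index(b)])

    def down_set(self, x: Combination, strict: bool = False) -> frozenset[Combination]:
        i = self.index(x)
        below = {self.elements[j] for j in np.flatnonzero(self.leq[:, i])}
        if strict:
            below.discard(x)
        return frozenset(below)

    def up_set(self, x: Combination, strict: bool = False) -> frozenset[Combination]:
        i = self.index(x)
        above = {self.elements[j] for j in np.flatnonzero(self.leq[i, :])}
        if strict:
            above.discard(x)
        return frozenset(above)

    def restrict(self, elements: Iterable[Combination]) -> "CombinationPoset":
        """Induced subposet on the given elements."""
        elems = list(elements)
        for e in elems:
            self.index(e)  # membership check
        return CombinationPoset(self.levels_per_agent, elems)

    def mask_to_set(self, mask: int) -> frozenset[Combination]:
        return frozenset(self.elements[i] for i in _bits(mask))


def _row_mask(row: np.ndarray) -> int:
    mask = 0
    for j in np.flatnonzero(row):
        mask |= 1 << int(j)
    return mask


def _bits(mask: int) -> Iterator[int]:
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def build_grid_poset(
    levels_per_agent: Sequence[int],
    subset: Optional[Iterable[Combination]] = None,
) -> CombinationPoset:
    """Poset on the full dose grid, or on a subset with the inherited order."""
    levels = tuple(int(l) for l in levels_per_agent)
    if subset is None:
        elements: Iterable[Combination] = itertools.product(
            *(range(1, l + 1) for l in levels)
        )
    else:
        elements = [tuple(int(i) for i in c) for c in subset]
    return CombinationPoset(levels, elements)


@dataclass(frozen=True)
class Ordering:
    """One complete toxicity ordering: position ``l`` is the l-th least toxic.

    ``sequence`` must be a permutation of the poset elements it is used with;
    whether it actually respects the dominance order is checked by
    :func:`is_linear_extension`.
    """

    sequence: tuple[Combination, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", tuple(tuple(c) for c in self.sequence))
        if len(set(self.sequence)) != len(self.sequence):
            raise ValueError("ordering contains a repeated combination")

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self) -> Iterator[Combination]:
        return iter(self.sequence)

    def at(self, l: int) -> Combination:
        """The combination at 1-based position ``l`` (the l-th least toxic)."""
        if not 1 <= l <= len(self.sequence):
            raise IndexError(f"position {l} out of range 1..{len(self.sequence)}")
        return self.sequence[l - 1]

    def position(self, combo: Combination) -> int:
        """1-based position of ``combo`` in this ordering."""
        combo = tuple(combo)
        try:
            return self.sequence.index(combo) + 1
        except ValueError:
            raise KeyError(f"{combo} not in ordering") from None

    def labels(self) -> tuple[str, ...]:
        return tuple(format_combination(c) for c in self.sequence)


class OrderingList(list):
    """List of orderings; ``truncated`` flags an enumeration stopped at a cap."""

    truncated: bool = False


def is_linear_extension(ordering: Ordering, poset: CombinationPoset) -> bool:
    """True iff the ordering respects the dominance order of ``poset``.

    Raises ``ValueError`` if the ordering is not a permutation of the
    poset's elements.
    """
    if set(ordering.sequence) != set(poset.elements) or len(ordering) != len(poset):
        raise ValueError("ordering does not cover exactly the poset's elements")
    pos = {c: i for i, c in enumerate(ordering.sequence)}
    n = len(poset)
    for i in range(n):
        for j in np.flatnonzero(poset.leq[i]):
            if pos[poset.elements[i]] > pos[poset.elements[int(j)]]:
                return False
    return True


def enumerate_linear_extensions(
    poset: CombinationPoset, cap: Optional[int] = None
) -> OrderingList:
    """All linear extensions, in lexicographic depth-first order.

    At every step the smallest (by coordinate tuple) available minimal
    element is explored first, so the index of each ordering in the result
    is deterministic.  With ``cap`` given, enumeration stops after ``cap``
    orderings and the result is flagged ``truncated``.
    """
    n = len(poset)
    down = poset._down_masks
    out = OrderingList()
    full = (1 << n) - 1
    prefix: list[int] = []

    def rec(placed: int) -> bool:
        if placed == full:
            out.append(Ordering(tuple(poset.elements[i] for i in prefix)))
            return cap is not None and len(out) >= cap
        for i in range(n):
            bit = 1 << i
            if placed & bit or (down[i] & ~placed):
                continue
            prefix.append(i)
            stop = rec(placed | bit)
            prefix.pop()
            if stop:
                return True
        return False

    out.truncated = rec(0)
    return out


def _ideal_masks(poset: CombinationPoset, max_ideals: int = DEFAULT_MAX_IDEALS) -> list[int]:
    """All order ideals as bitmasks, in breadth-first (cardinality) order."""
    n = len(poset)
    down = poset._down_masks
    seen = {0}
    frontier = [0]
    order = [0]
    while frontier:
        nxt = []
        for mask in frontier:
            for i in range(n):
                bit = 1 << i
                if mask & bit or (down[i] & ~mask):
                    continue
                new = mask | bit
                if new not in seen:
                    seen.add(new)
                    nxt.append(new)
                    if len(seen) > max_ideals:
                        raise PosetSizeError(
                            f"ideal lattice exceeds {max_ideals} ideals"
                        )
        order.extend(sorted(nxt))
        frontier = nxt
    return order


def enumerate_ideals(
    poset: CombinationPoset, max_ideals: int = DEFAULT_MAX_IDEALS
) -> list[frozenset[Combination]]:
    """All down-closed subsets (order ideals), including the empty and full set."""
    return [poset.mask_to_set(m) for m in _ideal_masks(poset, max_ideals)]


def count_ideals(poset: CombinationPoset, max_ideals: int = DEFAULT_MAX_IDEALS) -> int:
    return len(_ideal_masks(poset, max_ideals))


def count_linear_extensions(
    poset: CombinationPoset, max_ideals: int = DEFAULT_MAX_IDEALS
) -> int:
    """Exact number of linear extensions, via DP on the ideal lattice.

    The extensions are in bijection with the maximal chains of the ideal
    lattice: ``f(I) = sum of f(I \\ {x})`` over elements ``x`` maximal in
    the ideal ``I``, with ``f(empty) = 1``.  Exact integer arithmetic.
    """
    n = len(poset)
    up = poset._up_masks
    masks = _ideal_masks(poset, max_ideals)
    f: dict[int, int] = {0: 1}
    for mask in masks:
        if mask == 0:
            continue
        total = 0
        for i in _bits(mask):
            if up[i] & mask:  # i not maximal in this ideal
                continue
            total += f[mask ^ (1 << i)]
        f[mask] = total
    return f[(1 << n) - 1]


def incomparable_subposet(poset: CombinationPoset, x: Combination) -> CombinationPoset:
    """Induced poset on the elements neither dominating nor dominated by ``x``."""
    i = poset.index(x)
    keep = [
        e
        for j, e in enumerate(poset.elements)
        if not poset.leq[i, j] and not poset.leq[j, i]
    ]
    return CombinationPoset(poset.levels_per_agent, keep)


def random_linear_extension(
    poset: CombinationPoset, rng: np.random.Generator
) -> Ordering:
    """A seeded random linear extension (uniform choice among minimal available
    elements at each step; not uniform over extensions, which is not needed)."""
    n = len(poset)
    down = poset._down_masks
    placed = 0
    seq: list[Combination] = []
    for _ in range(n):
        avail = [
            i
            for i in range(n)
            if not (placed >> i) & 1 and not (down[i] & ~placed)
        ]
        pick = avail[int(rng.integers(len(avail)))]
        seq.append(poset.elements[pick])
        placed |= 1 << pick
    return Ordering(tuple(seq))
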