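"""Operating characteristics: PCS estimation, bundled scenarios, and a
synthetic monotone scenario generator.

PCS (percentage of correct selection) is the fraction of simulated trials
whose final recommendation equals the scenario's true MTC.  The summary
across scenarios is the geometric mean, which penalises a specification that
collapses under any single scenario more than the arithmetic mean would.

The bundled fixtures are the twelve benchmark toxicity scenarios on the
motivating 12-combination triple-combination grid: every combination is the
MTC (at probability exactly 0.25) in exactly one scenario, and neighbouring
probabilities differ by mixtures of 0.10 and 0.15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .design import DesignConfig, run_trials
from .poset import (
    Combination,
    CombinationPoset,
    Ordering,
    build_grid_poset,
    random_linear_extension,
)
from .scenarios import OrderScenario, ToxicityScenario, enumerate_order_scenarios

#: the 12 combinations of the motivating three-drug trial
MOTIVATING_SUBSET: tuple[Combination, ...] = (
    (1, 1, 1),
    (1, 2, 1),
    (2, 2, 1),
    (2, 2, 2),
    (2, 3, 1),
    (2, 3, 2),
    (2, 4, 1),
    (2, 4, 2),
    (3, 3, 1),
    (3, 3, 2),
    (3, 4, 1),
    (3, 4, 2),
)

#: calibrated toxicity skeleton for the motivating trial (12 positions)
MOTIVATING_SKELETON: tuple[float, ...] = (
    0.0003,
    0.02,
    0.04,
    0.08,
    0.19,
    0.25,
    0.28,
    0.31,
    0.38,
    0.44,
    0.50,
    0.56,
)

#: rule-based stage-1 escalation path of the motivating trial
MOTIVATING_STAGE1_PATH: tuple[Combination, ...] = (
    (1, 1, 1),
    (1, 2, 1),
    (2, 2, 1),
    (2, 3, 1),
    (3, 3, 1),
    (2, 4, 1),
    (3, 4, 1),
    (2, 2, 2),
    (2, 3, 2),
    (3, 3, 2),
    (2, 4, 2),
    (3, 4, 2),
)

MOTIVATING_TTL = 0.25


def motivating_poset() -> CombinationPoset:
    """The 12-combination poset of the motivating three-drug trial."""
    return build_grid_poset((3, 4, 2), MOTIVATING_SUBSET)


def motivating_config(
    orderings: Sequence[Ordering],
    n_max: int = 60,
    priors=None,
    estimation: str = "ml",
) -> DesignConfig:
    """Benchmark design configuration of the motivating trial."""
    return DesignConfig(
        poset=motivating_poset(),
        ttl=MOTIVATING_TTL,
        skeleton=np.array(MOTIVATING_SKELETON),
        orderings=tuple(orderings),
        stage1_path=Ordering(MOTIVATING_STAGE1_PATH),
        n_max=n_max,
        priors=priors,
        estimation=estimation,
    )


def table3_scenarios() -> list[ToxicityScenario]:
    """The twelve bundled benchmark toxicity scenarios, validated on load."""
    from .fileio import read_scenario_csv

    poset = motivating_poset()
    out = []
    root = resources.files("pocrmkit").joinpath("data/table3")
    for r in range(1, 13):
        with resources.as_file(root.joinpath(f"R{r:02d}.csv")) as path:
            out.append(read_scenario_csv(path, poset, name=f"R({r})"))
    return out


@dataclass(frozen=True)
class PcsEstimate:
    """Monte-Carlo estimate of the probability of correct MTC selection."""

    scenario: str
    n_patients: int
    n_sims: int
    pcs: float
    se: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pcs <= 1.0:
            raise ValueError("pcs must lie in [0, 1]")


def estimate_pcs(
    scenario: ToxicityScenario,
    config: DesignConfig,
    n_sims: int,
    seed: int = 0,
    ttl: Optional[float] = None,
) -> PcsEstimate:
    """Fraction of simulated trials recommending the scenario's true MTC."""
    from .scenarios import find_mtc

    ttl = config.ttl if ttl is None else ttl
    mtc_idx = config.poset.index(find_mtc(scenario, ttl))
    batch = run_trials(scenario, config, n_sims=n_sims, rng_seed=seed)
    pcs = float(np.mean(batch.recommended_idx == mtc_idx))
    return PcsEstimate(
        scenario=scenario.name,
        n_patients=config.n_max,
        n_sims=n_sims,
        pcs=pcs,
        se=math.sqrt(pcs * (1.0 - pcs) / n_sims),
    )


def pcs_curve(
    scenario: ToxicityScenario,
    config: DesignConfig,
    n_grid: Sequence[int],
    n_sims: int,
    seed: int = 0,
) -> list[PcsEstimate]:
    """One PCS estimate per sample size, on a shared scenario."""
    return [
        estimate_pcs(scenario, config.with_n_max(int(n)), n_sims, seed=seed + k)
        for k, n in enumerate(n_grid)
    ]


def geometric_mean_pcs(values: Sequence[float]) -> float:
    """Geometric mean of PCS values (percent or proportion scale alike)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or (values <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(values))))


def generate_scenario(
    poset: CombinationPoset,
    ttl: float,
    target_os: Optional[OrderScenario] = None,
    gap: float = 0.05,
    rng_seed: int = 0,
    name: str = "synthetic",
) -> ToxicityScenario:
    """Synthetic monotone toxicity scenario realising a given order-scenario.

    The MTC receives probability exactly ``ttl``; below-set members receive
    distinct probabilities in (0, ttl - gap) increasing along a random linear
    extension of the below-set, the remaining combinations distinct
    probabilities in (ttl + gap, 1) along a random extension of the rest.
    The output is monotone-consistent and maps back to ``target_os``.  With
    no ``target_os`` an order-scenario is drawn uniformly from the full
    enumeration first.
    """
    if not 0.0 < ttl < 1.0:
        raise ValueError("ttl must lie in (0, 1)")
    if gap <= 0 or ttl - gap <= 0 or ttl + gap >= 1:
        raise ValueError("infeasible spacing: need 0 < gap, 0 < ttl-gap, ttl+gap < 1")
    rng = np.random.default_rng(rng_seed)
    if target_os is None:
        all_os = enumerate_order_scenarios(poset)
        target_os = all_os[int(rng.integers(len(all_os)))]
    target_os.validate(poset)
    probs: dict[Combination, float] = {target_os.mtc: ttl}
    below = sorted(target_os.below)
    rest = [e for e in poset.elements if e != target_os.mtc and e not in target_os.below]
    if below:
        ext = random_linear_extension(poset.restrict(below), rng)
        vals = np.sort(rng.uniform(1e-6, ttl - gap, size=len(below)))
        while len(np.unique(vals)) < len(vals):  # pragma: no cover - measure zero
            vals = np.sort(rng.uniform(1e-6, ttl - gap, size=len(below)))
        for c, v in zip(ext.sequence, vals):
            probs[c] = float(v)
    if rest:
        ext = random_linear_extension(poset.restrict(rest), rng)
        vals = np.sort(rng.uniform(ttl + gap, 1.0 - 1e-6, size=len(rest)))
        while len(np.unique(vals)) < len(vals):  # pragma: no cover
            vals = np.sort(rng.uniform(ttl + gap, 1.0 - 1e-6, size=len(rest)))
        for c, v in zip(ext.sequence, vals):
            probs[c] = float(v)
    return ToxicityScenario(poset, probs, name=name)
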