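"""File round-trips: orderings as CSV, scenarios as CSV, order-scenarios as
JSON, design configs as YAML, and run manifests.

Combinations are written everywhere as 1-based dot-separated labels
("i.j.k"); orderings are one CSV row per ordering with columns
``pos1..posL`` in increasing-toxicity position order.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .poset import (
    CombinationPoset,
    Ordering,
    OrderingList,
    build_grid_poset,
    format_combination,
    is_linear_extension,
    parse_combination,
)
from .scenarios import OrderScenario, ToxicityScenario

PathLike = Union[str, Path]


def write_orderings(orderings: Sequence[Ordering], path: PathLike) -> None:
    """Write orderings as CSV rows of combination labels, header pos1..posL."""
    orderings = list(orderings)
    if orderings:
        L = len(orderings[0])
        cols = [f"pos{l}" for l in range(1, L + 1)]
        df = pd.DataFrame([o.labels() for o in orderings], columns=cols)
    else:
        df = pd.DataFrame()
    df.to_csv(path, index=False)


def read_orderings(
    path: PathLike,
    poset: Optional[CombinationPoset] = None,
    strict: bool = True,
) -> OrderingList:
    """Read orderings from CSV; empty file yields an empty list.

    Rows with repeated combinations always raise.  With a poset given,
    rows that are not linear extensions raise when ``strict`` (default) and
    are kept otherwise.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return OrderingList()
    out = OrderingList()
    for _, row in df.iterrows():
        seq = tuple(parse_combination(cell) for cell in row)
        ordering = Ordering(seq)  # raises on repeats
        if poset is not None and strict and not is_linear_extension(ordering, poset):
            raise ValueError(
                f"row {ordering.labels()} does not respect the partial order"
            )
        out.append(ordering)
    return out


def read_scenario_csv(
    path: PathLike, poset: CombinationPoset, name: str = ""
) -> ToxicityScenario:
    """Read one toxicity scenario (columns ``combination``, ``prob``);
    validation (domain, range, monotone-consistency) happens on construction
    and names the offending pair."""
    df = pd.read_csv(path)
    probs = {
        parse_combination(str(row["combination"])): float(row["prob"])
        for _, row in df.iterrows()
    }
    return ToxicityScenario(poset, probs, name=name or Path(path).stem)


def read_scenarios(path: PathLike, poset: CombinationPoset) -> list[ToxicityScenario]:
    """Read all scenario CSVs from a file or directory."""
    p = Path(path)
    files = sorted(p.glob("*.csv")) if p.is_dir() else [p]
    return [read_scenario_csv(f, poset) for f in files]


def write_scenario_csv(scenario: ToxicityScenario, path: PathLike) -> None:
    pd.DataFrame(
        {
            "combination": [format_combination(c) for c in scenario.poset.elements],
            "prob": [scenario.probs[c] for c in scenario.poset.elements],
        }
    ).to_csv(path, index=False)


def order_scenario_to_dict(os: OrderScenario) -> dict:
    return {
        "mtc": format_combination(os.mtc),
        "nu": os.nu,
        "below": sorted(format_combination(c) for c in os.below),
    }


def order_scenario_from_dict(d: dict) -> OrderScenario:
    os = OrderScenario(
        mtc=parse_combination(d["mtc"]),
        below=frozenset(parse_combination(c) for c in d["below"]),
    )
    if "nu" in d and int(d["nu"]) != os.nu:
        raise ValueError(f"inconsistent nu {d['nu']} for below set of size {len(os.below)}")
    return os


def write_order_scenarios(scenarios: Sequence[OrderScenario], path: PathLike) -> None:
    with open(path, "w") as f:
        json.dump([order_scenario_to_dict(os) for os in scenarios], f, indent=1)


def read_order_scenarios(path: PathLike) -> list[OrderScenario]:
    with open(path) as f:
        data = json.load(f)
    return [order_scenario_from_dict(d) for d in data]


def poset_from_config(cfg: dict) -> CombinationPoset:
    """Build a poset from a config mapping: ``levels`` plus optional ``subset``."""
    subset = cfg.get("subset")
    return build_grid_poset(
        cfg["levels"],
        None if subset is None else [tuple(c) for c in subset],
    )


def load_yaml(path: PathLike) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def sha256_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for a CLI run: config snapshot, seeds, package
    version, per-command timing, and digests of every produced file."""

    command: str
    config: dict
    seed: Optional[int] = None
    version: str = ""
    started: float = field(default_factory=time.time)
    elapsed_s: float = 0.0
    outputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def record_output(self, path: PathLike) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def finish(self) -> None:
        self.elapsed_s = time.time() - self.started

    def write(self, path: PathLike) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "command": self.command,
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "elapsed_s": round(self.elapsed_s, 3),
                    "outputs": self.outputs,
                },
                f,
                indent=1,
            )
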