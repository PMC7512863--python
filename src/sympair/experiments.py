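"""Replicated experiment drivers: control conditions and the pair-age sweep.

Two study designs are scripted here:

* ``run_controls`` — the 2x2 of {sexual selection on/off} x {lifelong pairing
  on/off} on one landscape, with shared seeds so every condition starts from
  the same founder population.  With both mechanisms off the model degenerates
  to random mating within nodes.
* ``run_sweep`` — replicated runs across a set of maximum pair ages (0 means
  pairs dissolve right after their single reproduction), tracking the
  centroid-distance diversity and detected species count over time.

Outcomes are summarized ordinally (per-replicate orderings, replicate
majorities) rather than as point estimates: the reference results for these
designs are figures, and only the direction of the effects is a defensible
comparison.  The module-level ``SCALED`` defaults keep a full replicated
suite in the minutes range; they shrink the run length and founder count
while preserving the nominal per-capita share and the qualitative orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import RunResult, SimulationConfig, run
from .errors import ConfigurationError

__all__ = [
    "SweepSpec",
    "scaled_config",
    "run_sweep",
    "run_controls",
    "tidy_results",
    "final_epoch_mean",
    "CONTROL_CONDITIONS",
]

#: scaled study conditions used by the replicated suites
SCALED = {
    "steps": 2000,
    "initial_population": 150,
    "total_resource": 750.0,   # keeps the nominal share at 5 resource units
    "snapshot_every": 200,
}

#: names of the four control conditions (sexual selection, pairing)
CONTROL_CONDITIONS: dict[str, tuple[bool, bool]] = {
    "no_selection_no_pairs": (False, False),
    "no_selection_pairs": (False, True),
    "selection_no_pairs": (True, False),
    "selection_pairs": (True, True),
}

_METRICS = ["N", "D0", "D0.5", "D1", "D2", "centroid_distance", "n_species"]


def scaled_config(landscape: str = "rastrigin", **overrides) -> SimulationConfig:
    """A reduced-size configuration for replicated experiment suites."""
    return SimulationConfig(landscape=landscape).with_overrides(**{**SCALED, **overrides})


@dataclass(frozen=True)
class SweepSpec:
    """A replicated sweep over maximum pair ages."""

    landscape: str
    max_pair_ages: tuple[int, ...]
    replicates: int
    base_config: SimulationConfig
    seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError(f"replicates must be >= 1, got {self.replicates}")
        if len(self.seeds) != self.replicates:
            raise ConfigurationError(
                f"need one seed per replicate ({self.replicates}), got {len(self.seeds)}"
            )
        if len(set(self.seeds)) != len(self.seeds):
            raise ConfigurationError("seeds must be distinct")
        if len(self.max_pair_ages) == 0:
            raise ConfigurationError("max_pair_ages must be nonempty")

    @classmethod
    def from_seed(
        cls,
        landscape: str,
        max_pair_ages: Sequence[int],
        replicates: int,
        seed: int,
        base_config: Optional[SimulationConfig] = None,
    ) -> "SweepSpec":
        """Derive distinct replicate seeds from one master seed."""
        seeds = tuple(int(s) for s in np.random.SeedSequence(seed).generate_state(replicates) % (2**31))
        base = base_config if base_config is not None else scaled_config(landscape)
        return cls(
            landscape=landscape,
            max_pair_ages=tuple(int(a) for a in max_pair_ages),
            replicates=replicates,
            base_config=base,
            seeds=seeds,
        )


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run every (max_pair_age, replicate) cell; return a tidy results table.

    Columns: condition (the max pair age), replicate, seed, step, metric,
    value.  A pair age of 0 disables persistent pairs; with one replicate and
    one pair age this reduces to a single ``engine.run``.
    """
    frames = []
    for age in spec.max_pair_ages:
        for rep, seed in enumerate(spec.seeds):
            cfg = spec.base_config.with_overrides(
                landscape=spec.landscape, max_pair_age=age, pairing=age > 0, seed=seed
            )
            result = run(cfg)
            frames.append(tidy_results(result, condition=f"maxPairAge={age}", replicate=rep, seed=seed))
    return pd.concat(frames, ignore_index=True)


def run_controls(
    landscape: str,
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> dict[str, RunResult]:
    """The 2x2 mechanism controls with a shared seed.

    Lifelong pairing is encoded as ``max_pair_age = steps`` (a pair persists
    until a member dies); pairing off as ``max_pair_age = 0``.  All four
    conditions share the founder population because initialization draws do
    not depend on the toggles.
    """
    base = config if config is not None else scaled_config(landscape)
    if seed is not None:
        base = base.with_overrides(seed=seed)
    results: dict[str, RunResult] = {}
    for label, (selection, pairing) in CONTROL_CONDITIONS.items():
        cfg = base.with_overrides(
            landscape=landscape,
            sexual_selection=selection,
            pairing=pairing,
            max_pair_age=base.steps if pairing else 0,
        )
        results[label] = run(cfg)
    return results


def tidy_results(result: RunResult, condition: str, replicate: int = 0, seed: Optional[int] = None) -> pd.DataFrame:
    """Melt one run's diversity series into (condition, replicate, step, metric, value)."""
    df = result.diversity[["step"] + _METRICS].melt(id_vars="step", var_name="metric", value_name="value")
    df.insert(0, "condition", condition)
    df.insert(1, "replicate", replicate)
    df.insert(2, "seed", result.config.seed if seed is None else seed)
    return df


def final_epoch_mean(result: RunResult, metric: str = "centroid_distance", window: int = 500) -> float:
    """Mean of a diversity metric over the snapshots of the last ``window`` steps."""
    df = result.diversity
    tail = df[df["step"] > result.config.steps - window]
    if tail.empty:
        tail = df.tail(1)
    return float(tail[metric].mean())
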