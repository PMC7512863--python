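"""Step scheduler, configuration and run orchestration.

Each simulation step executes a fixed phase order:

(a) upkeep — every agent returns a small fixed maintenance amount to the pool;
(b) dispensing — a fraction of the pool is split equally over occupied nodes,
    then within each node by fitness-derived quality weights (margins above
    the local best, on the landscape's global value scale);
(c) pair aging — pair ages advance; pairs past their maximum age (or with a
    dead member) dissolve;
(d) courtship — in every node, unpaired females (in seeded random order) pick
    among the unpaired males of that node; with sexual selection on the female
    accepts with a probability falling in the preference distance, otherwise
    always; accepted couples form pairs;
(e) reproduction — every pair whose members are both ready produces a brood of
    two (with ``max_pair_age = 0`` all pairs dissolve at the end of the phase,
    so each pairing yields at most one brood);
(f) migration — every agent still unpaired is searching for a partner and
    moves to a random neighbouring node, paying the migration cost; whole
    pairs move spontaneously with a small per-step probability;
(g) deaths — agents at or below the death floor return their resource to the
    pool and are removed, dissolving their pairs; ages and the step counter
    advance.

Partner search is the model's main mortality channel: an unpaired agent pays
the migration cost every step until it is accepted, so choosy females, scarce
candidates and dissolved pairs all translate into resource drain, while the
members of a standing pair are sheltered.

All randomness flows through one generator in this documented order, so a run
is bit-reproducible from its (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, Iterator, MutableMapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import diversity, landscapes, mating, world
from .errors import ConfigurationError
from .genetics import Genotype, VariationParams
from .landscapes import LandscapeSpec
from .mating import Agent, Pair, Sex
from .world import EnvironmentGraph, ResourceLedger

__all__ = [
    "SimulationConfig",
    "WorldState",
    "PopulationSnapshot",
    "RunResult",
    "initialize",
    "step",
    "run",
    "snapshots_frame",
]

SNAPSHOT_COLUMNS = [
    "step", "id", "sex", "node", "x1", "x2",
    "sigma1", "sigma2", "resource", "pair_id", "age", "pool",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of a run; defaults are the reference study conditions."""

    landscape: str = "rastrigin"
    grid_rows: int = 4
    grid_cols: int = 4
    initial_population: int = 200
    total_resource: float = 1000.0
    dispense_rate: float = 0.1
    upkeep: float = 0.01          # fixed per-step cost, as a fraction of the nominal share
    max_pair_age: int = 5000
    mut_prob: float = 0.1
    rec_prob: float = 0.8
    min_rep_res: float = 0.5
    female_rep_cost: float = 0.4
    male_rep_cost: float = 0.2
    mig_cost: float = 0.05
    move_prob: float = 0.05
    sexual_selection: bool = True
    pairing: bool = True
    steps: int = 5000
    seed: int = 0
    snapshot_every: int = 500
    sigma_init_fraction: float = 0.1
    death_floor: float = 0.01     # death when resource <= death_floor * nominal share
    acceptance_scale_fraction: float = 0.08   # choosiness scale, fraction of the domain diagonal
    offspring_sex_rule: str = "balanced"
    kmax: int = 10

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fractions = [
            "dispense_rate", "upkeep", "mut_prob", "rec_prob", "min_rep_res",
            "female_rep_cost", "male_rep_cost", "mig_cost", "move_prob",
        ]
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.steps < 0:
            raise ConfigurationError(f"steps must be >= 0, got {self.steps}")
        if self.initial_population < 2 or self.initial_population % 2 != 0:
            raise ConfigurationError(
                f"initial_population must be even and >= 2 (sex balance), got {self.initial_population}"
            )
        if self.total_resource <= 0.0:
            raise ConfigurationError(f"total_resource must be positive, got {self.total_resource}")
        if self.max_pair_age < 0:
            raise ConfigurationError(f"max_pair_age must be >= 0, got {self.max_pair_age}")
        if self.snapshot_every < 1:
            raise ConfigurationError(f"snapshot_every must be >= 1, got {self.snapshot_every}")
        if self.sigma_init_fraction <= 0.0:
            raise ConfigurationError(f"sigma_init_fraction must be positive, got {self.sigma_init_fraction}")
        if self.acceptance_scale_fraction <= 0.0:
            raise ConfigurationError(
                f"acceptance_scale_fraction must be positive, got {self.acceptance_scale_fraction}"
            )
        if self.offspring_sex_rule not in ("balanced", "coin"):
            raise ConfigurationError(
                f"offspring_sex_rule must be 'balanced' or 'coin', got {self.offspring_sex_rule!r}"
            )
        landscapes.get_landscape(self.landscape)

    @property
    def nominal_share(self) -> float:
        return self.total_resource / self.initial_population

    @property
    def effective_max_pair_age(self) -> int:
        """``max_pair_age``, forced to 0 when pairing is switched off."""
        return self.max_pair_age if self.pairing else 0

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must be a flat key-value mapping")
        return cls().with_overrides(**data).with_overrides(**overrides)


class _AgentResources(MutableMapping):
    """Ledger view of the agents' holdings; Agent.resource is the single store."""

    def __init__(self, agents: dict[int, Agent]):
        self._agents = agents

    def __getitem__(self, key: int) -> float:
        return self._agents[key].resource

    def __setitem__(self, key: int, value: float) -> None:
        self._agents[key].resource = value

    def __delitem__(self, key: int) -> None:
        raise TypeError("agents are removed via the death phase, not the ledger")

    def __iter__(self) -> Iterator[int]:
        return iter(self._agents)

    def __len__(self) -> int:
        return len(self._agents)


@dataclass
class WorldState:
    """Mutable state of a running simulation."""

    graph: EnvironmentGraph
    landscape: LandscapeSpec
    config: SimulationConfig
    variation: VariationParams
    agents: dict[int, Agent]
    pairs: dict[int, Pair]
    node_agents: dict[int, set[int]]
    ledger: ResourceLedger
    rng: np.random.Generator
    fitness_scale: float = 1.0      # landscape global value range (weights scale)
    acceptance_scale: float = 1.0   # choosiness scale in genetic space
    step_count: int = 0
    next_agent_id: int = 0
    next_pair_id: int = 0

    @property
    def nominal_share(self) -> float:
        return self.config.nominal_share

    def conservation_error(self) -> float:
        """Relative drift of pool + agent holdings from the configured total."""
        return abs(self.ledger.total() - self.config.total_resource) / self.config.total_resource


@dataclass(frozen=True)
class PopulationSnapshot:
    """Pure copy of the per-agent state at one step, plus the pool level."""

    step: int
    pool: float
    agents: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.agents)

    def points(self) -> np.ndarray:
        """Genotype x-coordinates as an (n, 2) array (the genetic space)."""
        return self.agents[["x1", "x2"]].to_numpy()


@dataclass(frozen=True)
class RunResult:
    config: SimulationConfig
    snapshots: list[PopulationSnapshot]
    diversity: pd.DataFrame

    @property
    def final(self) -> PopulationSnapshot:
        return self.snapshots[-1]


def initialize(config: SimulationConfig) -> WorldState:
    """Seeded founder population: uniform genotypes, equal shares, balanced sexes."""
    config.validate()
    graph = world.torus_grid(config.grid_rows, config.grid_cols)
    spec = landscapes.get_landscape(config.landscape)
    rng = np.random.default_rng(config.seed)
    n = config.initial_population
    lo = np.asarray(spec.lower_bounds)
    width = np.asarray(spec.widths)
    sigma0 = tuple(config.sigma_init_fraction * w for w in width)

    node_idx = rng.integers(0, len(graph.node_ids), size=n)
    xs = lo + rng.random((n, 2)) * width

    agents: dict[int, Agent] = {}
    node_agents: dict[int, set[int]] = {node: set() for node in graph.node_ids}
    share = config.nominal_share
    for i in range(n):
        x = (float(xs[i, 0]), float(xs[i, 1]))
        node = graph.node_ids[int(node_idx[i])]
        agent = Agent(
            id=i,
            sex=Sex.FEMALE if i % 2 == 0 else Sex.MALE,
            genotype=Genotype(x=x, sigma=sigma0),
            resource=share,
            node=node,
            fitness=landscapes.evaluate(spec, x),
        )
        agents[i] = agent
        node_agents[node].add(i)

    tau0, tau = VariationParams.for_dimension(2).tau0, VariationParams.for_dimension(2).tau
    variation = VariationParams(tau0=tau0, tau=tau, mut_prob=config.mut_prob, rec_prob=config.rec_prob)
    ledger = ResourceLedger(pool=0.0, per_agent=_AgentResources(agents))
    return WorldState(
        graph=graph,
        landscape=spec,
        config=config,
        variation=variation,
        agents=agents,
        pairs={},
        node_agents=node_agents,
        ledger=ledger,
        rng=rng,
        fitness_scale=landscapes.value_range(spec),
        acceptance_scale=config.acceptance_scale_fraction * landscapes.domain_diagonal(spec),
        next_agent_id=n,
    )


def step(state: WorldState, config: Optional[SimulationConfig] = None) -> WorldState:
    """Advance the world by one step through phases (a)-(g)."""
    cfg = config if config is not None else state.config
    rng = state.rng
    agents = state.agents
    ledger = state.ledger
    share = cfg.nominal_share
    max_age = cfg.effective_max_pair_age

    # (a) upkeep: a fixed maintenance amount per agent returns to the pool
    upkeep_amount = cfg.upkeep * share
    for aid in sorted(agents):
        world.pay_flat(ledger, aid, upkeep_amount)

    # (b) dispensing: split the step's budget equally over occupied nodes,
    # within each node by quality weights on the landscape's value scale
    occupied = [node for node in state.graph.node_ids if state.node_agents[node]]
    if occupied:
        budget = cfg.dispense_rate * ledger.pool
        per_node = budget / len(occupied)
        for node in occupied:
            ids = sorted(state.node_agents[node])
            w = world.quality_weights([agents[i].fitness for i in ids], scale=state.fitness_scale)
            world.dispense_amount(ledger, dict(zip(ids, (float(v) for v in w))), per_node)

    # (c) pair aging and dissolution (with ephemeral pairs the brood rule in
    # phase (e) dissolves them; here only widowed pairs are cleaned up)
    mating.age_and_dissolve_pairs(state, max_age if max_age > 0 else None)

    # (d) courtship and pair formation, node by node; an unpaired agent enters
    # the mating market when it becomes ready and stays in it (searching,
    # roaming, paying) until it is accepted into a pair or dies
    for aid in sorted(agents):
        agent = agents[aid]
        if (
            agent.pair_id is None
            and not agent.searching
            and mating.ready_for_reproduction(agent, cfg.min_rep_res, share)
        ):
            agent.searching = True
    for node in occupied:
        ids = sorted(state.node_agents[node])
        females = [
            agents[i] for i in ids
            if agents[i].sex is Sex.FEMALE and agents[i].pair_id is None and agents[i].searching
        ]
        males = [
            agents[i] for i in ids
            if agents[i].sex is Sex.MALE and agents[i].pair_id is None and agents[i].searching
        ]
        if not females or not males:
            continue
        if len(females) > 1:
            order = rng.permutation(len(females))
            females = [females[int(k)] for k in order]
        available = list(males)
        for female in females:
            if not available:
                break
            partner = mating.court(
                female, available, rng, cfg.sexual_selection, state.acceptance_scale
            )
            if partner is not None:
                mating.form_pair(female, partner, state)
                available.remove(partner)

    # (e) reproduction of ready pairs; with max_pair_age = 0 a pair dissolves
    # right after its first brood (its members must search anew every time)
    for pid in sorted(state.pairs):
        children = mating.reproduce(state.pairs[pid], state, rng)
        if max_age == 0 and children:
            mating.dissolve_pair(state, pid)

    # (f) migration: searchers roam for partners, paying the migration cost
    # every step; other singles and whole pairs move spontaneously
    idle: list[int] = []
    for aid in sorted(agents):
        agent = agents[aid]
        if agent.pair_id is not None:
            continue
        if agent.searching:
            nbrs = state.graph.neighbours(agent.node)
            target = nbrs[int(rng.integers(len(nbrs)))]
            world.migrate(state, agent, target, cfg.mig_cost)
        else:
            idle.append(aid)
    if idle:
        draws = rng.random(len(idle))
        for aid, u in zip(idle, draws):
            if u < cfg.move_prob:
                agent = agents[aid]
                nbrs = state.graph.neighbours(agent.node)
                target = nbrs[int(rng.integers(len(nbrs)))]
                world.migrate(state, agent, target, cfg.mig_cost)
    pair_ids = sorted(state.pairs)
    if pair_ids:
        draws = rng.random(len(pair_ids))
        for pid, u in zip(pair_ids, draws):
            if u < cfg.move_prob:
                pair = state.pairs[pid]
                node = agents[pair.female_id].node
                nbrs = state.graph.neighbours(node)
                target = nbrs[int(rng.integers(len(nbrs)))]
                world.migrate(state, pair, target, cfg.mig_cost)

    # (g) deaths, aging, step counter
    floor = cfg.death_floor * share
    for aid in sorted(agents):
        agent = agents[aid]
        if agent.resource <= floor:
            ledger.pool += agent.resource
            agent.resource = 0.0
            state.node_agents[agent.node].discard(aid)
            del agents[aid]
            if agent.pair_id is not None and agent.pair_id in state.pairs:
                mating.dissolve_pair(state, agent.pair_id)
    for agent in agents.values():
        agent.age += 1
    state.step_count += 1
    return state


def take_snapshot(state: WorldState) -> PopulationSnapshot:
    rows = []
    for aid in sorted(state.agents):
        a = state.agents[aid]
        rows.append((
            state.step_count, a.id, a.sex.value, a.node,
            a.genotype.x[0], a.genotype.x[1],
            a.genotype.sigma[0], a.genotype.sigma[1],
            a.resource, -1 if a.pair_id is None else a.pair_id, a.age,
            state.ledger.pool,
        ))
    frame = pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)
    return PopulationSnapshot(step=state.step_count, pool=state.ledger.pool, agents=frame)


def _diversity_row(snapshot: PopulationSnapshot, kmax: int) -> dict:
    report = diversity.diversity_report(snapshot.points(), kmax=kmax)
    return {
        "step": snapshot.step,
        "N": snapshot.n,
        "pool": snapshot.pool,
        "D0": report.d0,
        "D0.5": report.d05,
        "D1": report.d1,
        "D2": report.d2,
        "centroid_distance": report.centroid_distance,
        "n_species": report.k,
    }


def run(
    config: SimulationConfig,
    log_fn: Optional[Callable[[dict], None]] = None,
) -> RunResult:
    """Simulate ``config.steps`` steps, snapshotting every ``snapshot_every``.

    Every snapshot (including the founder population at step 0) carries a full
    diversity report: detected species count, Hill numbers of the species
    abundances, and the centroid-distance diversity of the genotypes.
    """
    state = initialize(config)
    snapshots = [take_snapshot(state)]
    rows = [_diversity_row(snapshots[0], config.kmax)]
    if log_fn is not None:
        log_fn(rows[-1])
    for t in range(1, config.steps + 1):
        step(state, config)
        if t % config.snapshot_every == 0:
            snap = take_snapshot(state)
            snapshots.append(snap)
            rows.append(_diversity_row(snap, config.kmax))
            if log_fn is not None:
                log_fn(rows[-1])
    return RunResult(config=config, snapshots=snapshots, diversity=pd.DataFrame(rows))


def snapshots_frame(snapshots: Sequence[PopulationSnapshot]) -> pd.DataFrame:
    """Concatenate snapshots into one tidy frame (one row per agent per step)."""
    if not snapshots:
        return pd.DataFrame(columns=SNAPSHOT_COLUMNS)
    return pd.concat([s.agents for s in snapshots], ignore_index=True)
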