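"""Graph environment and the closed resource economy.

The environment is an undirected, connected graph of nodes; an agent sees (and
can interact with) only the agents in its own node, and may migrate along
edges.  Selection is decentralized: a fixed total amount of resource circulates
between the environment pool and the agents.  The environment dispenses
resource to agents in proportion to fitness-derived quality weights; agents pay
resource back to the pool when they act (migration, upkeep).  The sum
``pool + Σ per-agent`` is invariant for the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, MutableMapping, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError, DomainError, StructuralError

__all__ = [
    "EnvironmentGraph",
    "torus_grid",
    "ResourceLedger",
    "quality_weights",
    "dispense",
    "dispense_amount",
    "pay_cost",
    "pay_flat",
    "migrate",
]

#: sharpness of the fitness-to-weight softmax (e-folds across the fitness scale)
QUALITY_SHARPNESS = 10.0


@dataclass(frozen=True)
class EnvironmentGraph:
    """Undirected, connected node graph with symmetric adjacency."""

    node_ids: tuple[int, ...]
    adjacency: Mapping[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        nodes = set(self.node_ids)
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if v not in nodes:
                    raise ConfigurationError(f"adjacency refers to unknown node {v!r}")
                if u not in self.adjacency.get(v, ()):
                    raise ConfigurationError(f"adjacency is not symmetric for edge ({u!r}, {v!r})")
        g = nx.Graph((u, v) for u, nbrs in self.adjacency.items() for v in nbrs)
        g.add_nodes_from(self.node_ids)
        if len(self.node_ids) > 1 and not nx.is_connected(g):
            raise ConfigurationError("environment graph must be connected")

    def neighbours(self, node: int) -> tuple[int, ...]:
        return self.adjacency[node]

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "EnvironmentGraph":
        nodes = tuple(sorted(g.nodes()))
        adjacency = {u: tuple(sorted(v for v in g.neighbors(u) if v != u)) for u in nodes}
        return cls(node_ids=nodes, adjacency=adjacency)


def torus_grid(rows: int = 4, cols: int = 4) -> EnvironmentGraph:
    """A rows x cols grid with wrap-around edges (no boundary artefacts).

    Nodes are integers ``r * cols + c``; every node has four neighbours for
    rows, cols >= 3 (fewer when wrap-around edges coincide).
    """
    if rows < 2 or cols < 2:
        raise ConfigurationError("torus grid needs rows >= 2 and cols >= 2")
    g = nx.grid_2d_graph(rows, cols, periodic=True)
    g = nx.relabel_nodes(g, {(r, c): r * cols + c for r, c in g.nodes()})
    return EnvironmentGraph.from_networkx(g)


@dataclass
class ResourceLedger:
    """The two places resource can live: the environment pool and the agents."""

    pool: float
    per_agent: MutableMapping[int, float] = field(default_factory=dict)

    def total(self) -> float:
        return self.pool + sum(self.per_agent.values())


def quality_weights(
    fitness_values: Sequence[float],
    scale: float | None = None,
    sharpness: float = QUALITY_SHARPNESS,
) -> np.ndarray:
    """Normalized resource-shares from raw (minimization) fitness values.

    The landscapes are minimization problems with negative ranges, so raw
    proportionality is ill-defined; instead each agent's weight is a softmax
    of its fitness margin above the local best::

        w_i ∝ exp(-sharpness * (f_i - min_j f_j) / scale)

    normalized to sum to one.  ``scale`` expresses the margin on the
    landscape's own units — the engine passes the landscape's global value
    range, so agents near *any* decent local optimum earn comparable shares
    while maladapted agents (e.g. recombinants stranded between niches) are
    starved.  Translation-invariant in fitness, strictly positive, uniform
    when all fitness values are equal.  Without an explicit scale the local
    spread is used.
    """
    if len(fitness_values) == 0:
        raise DomainError("quality_weights needs at least one fitness value")
    f = np.asarray(fitness_values, dtype=float)
    spread = f.max() - f.min()
    if scale is None:
        scale = spread
    if spread == 0.0 or scale <= 0.0:
        return np.full(len(f), 1.0 / len(f))
    w = np.exp(-sharpness * (f - f.min()) / scale)
    return w / w.sum()


def dispense_amount(ledger: ResourceLedger, weights: Mapping[int, float], amount: float) -> float:
    """Move ``amount`` from the pool to agents proportionally to ``weights``.

    Returns the amount actually moved (the float sum of the individual shares,
    so the ledger total is conserved to rounding).
    """
    moved = 0.0
    for agent_id, w in weights.items():
        share = amount * w
        ledger.per_agent[agent_id] = ledger.per_agent[agent_id] + share
        moved += share
    ledger.pool -= moved
    return moved


def dispense(ledger: ResourceLedger, weights: Mapping[int, float], dispense_rate: float) -> float:
    """Dispense ``dispense_rate`` of the current pool to agents by weight."""
    return dispense_amount(ledger, weights, dispense_rate * ledger.pool)


def pay_cost(ledger: ResourceLedger, agent_id: int, fraction: float) -> float:
    """Return ``fraction`` of an agent's resource to the environment pool."""
    if agent_id not in ledger.per_agent:
        raise StructuralError(f"unknown agent {agent_id!r}")
    if not 0.0 <= fraction <= 1.0:
        raise DomainError(f"cost fraction must lie in [0, 1], got {fraction}")
    paid = fraction * ledger.per_agent[agent_id]
    ledger.per_agent[agent_id] = ledger.per_agent[agent_id] - paid
    ledger.pool += paid
    return paid


def pay_flat(ledger: ResourceLedger, agent_id: int, amount: float) -> float:
    """Return a fixed ``amount`` (capped at the agent's holding) to the pool."""
    if agent_id not in ledger.per_agent:
        raise StructuralError(f"unknown agent {agent_id!r}")
    paid = min(amount, ledger.per_agent[agent_id])
    ledger.per_agent[agent_id] = ledger.per_agent[agent_id] - paid
    ledger.pool += paid
    return paid


def migrate(state, mover, target_node: int, mig_cost: float) -> bool:
    """Relocate an agent or a pair to an adjacent node, charging the move cost.

    ``mover`` is either an Agent or a Pair (a pair moves as one unit and both
    members pay).  Returns False (and leaves the state untouched) when the
    target is not adjacent to the current node.
    """
    members = _members_of(state, mover)
    current = members[0].node
    if target_node not in state.graph.neighbours(current):
        return False
    for agent in members:
        state.node_agents[agent.node].discard(agent.id)
        agent.node = target_node
        state.node_agents[target_node].add(agent.id)
        pay_cost(state.ledger, agent.id, mig_cost)
    return True


def _members_of(state, mover) -> list:
    if hasattr(mover, "female_id"):  # a Pair
        return [state.agents[mover.female_id], state.agents[mover.male_id]]
    return [mover]
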