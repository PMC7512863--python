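"""Sexual selection, pair formation and reproduction.

Females choose partners among the males searching in their own node; the
closer a male's displayed traits are to the female's preferences (Euclidean
distance in genetic space), the more likely he is picked, and the more likely
the pick is accepted.  An accepted couple forms a pair that co-migrates and
reproduces repeatedly until the pair exceeds its maximum age or a member
dies.  Reproduction creates two offspring by intermediate recombination and
self-adaptive mutation, funded by a resource transfer from the parents —
larger from the female, which is what makes females the choosy sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import math
from math import sqrt
from typing import Optional, Sequence

import numpy as np

from . import genetics, landscapes
from .errors import DomainError, StructuralError
from .genetics import Genotype

__all__ = [
    "Sex",
    "Agent",
    "Pair",
    "ready_for_reproduction",
    "preference_distance",
    "choice_weights",
    "choose_partner",
    "acceptance_probability",
    "court",
    "form_pair",
    "dissolve_pair",
    "age_and_dissolve_pairs",
    "reproduce",
]


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"


@dataclass(slots=True)
class Agent:
    """One individual: sex, genotype, resource holding, location and age."""

    id: int
    sex: Sex
    genotype: Genotype
    resource: float
    node: int
    pair_id: Optional[int] = None
    age: int = 0
    fitness: float = field(default=float("nan"))
    #: an agent starts searching when it becomes ready for reproduction and
    #: keeps searching (roaming, paying migration costs) until paired or dead
    searching: bool = False


@dataclass(slots=True)
class Pair:
    """A bound female/male couple sharing a node."""

    id: int
    female_id: int
    male_id: int
    pair_age: int = 0


def ready_for_reproduction(agent: Agent, min_rep_res: float, nominal_share: float) -> bool:
    """True iff the agent holds at least ``min_rep_res`` nominal shares.

    The nominal share is ``total_resource / initial_population``; the readiness
    threshold is inclusive.
    """
    return agent.resource >= min_rep_res * nominal_share


def preference_distance(female: Agent, male: Agent) -> float:
    """Euclidean distance between female preferences and male displayed traits."""
    if female.sex == male.sex:
        raise StructuralError("preference_distance needs one female and one male")
    fx, mx = female.genotype.x, male.genotype.x
    return sqrt(sum((a - b) ** 2 for a, b in zip(fx, mx)))


def choice_weights(distances: Sequence[float]) -> np.ndarray:
    """Selection probabilities from preference distances: w_i ∝ 1/(1+d_i).

    Strictly decreasing in distance and never zero, so there is always a small
    probability of choosing a poorly matching male (a small gene flow between
    emerging species).
    """
    if len(distances) == 0:
        raise DomainError("choice_weights needs at least one candidate")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0.0):
        raise DomainError("distances must be nonnegative")
    w = 1.0 / (1.0 + d)
    return w / w.sum()


def choose_partner(
    female: Agent,
    males_in_node: Sequence[Agent],
    rng,
    sexual_selection_on: bool = True,
) -> Optional[Agent]:
    """Sample a partner from the ready males of the female's node.

    With sexual selection on, sampling follows ``choice_weights`` over the
    preference distances; with it off, sampling is uniform.  Returns None when
    there are no candidates.  Exactly one uniform variate is consumed per call
    (none for an empty candidate set), drawn via inverse transform so runs are
    reproducible under a fixed seed.
    """
    n = len(males_in_node)
    if n == 0:
        return None
    if sexual_selection_on:
        w = choice_weights([preference_distance(female, m) for m in males_in_node])
    else:
        w = np.full(n, 1.0 / n)
    u = float(rng.random())
    idx = int(np.searchsorted(np.cumsum(w), u, side="right"))
    return males_in_node[min(idx, n - 1)]


def acceptance_probability(distance: float, scale: float) -> float:
    """Probability that a choosy female accepts a candidate at this distance.

    A Gaussian kernel on the preference distance: near-certain acceptance of a
    well-matching male, steeply falling beyond ``scale``.  Never exactly zero,
    so prolonged search can still end in a mismatched pairing — the small gene
    flow between emerging species.
    """
    if distance < 0.0 or scale <= 0.0:
        raise DomainError("acceptance needs distance >= 0 and scale > 0")
    return math.exp(-0.5 * (distance / scale) ** 2)


def court(
    female: Agent,
    males_in_node: Sequence[Agent],
    rng,
    sexual_selection_on: bool,
    acceptance_scale: float,
) -> Optional[Agent]:
    """One step of courtship: pick a candidate, then accept or reject him.

    With sexual selection on, the pick follows ``choice_weights`` and the
    female accepts with ``acceptance_probability`` of the picked male's
    distance; a rejection leaves her unpaired (searching on).  With sexual
    selection off every pick is accepted.  Returns the accepted male or None.
    """
    candidate = choose_partner(female, males_in_node, rng, sexual_selection_on)
    if candidate is None:
        return None
    if sexual_selection_on:
        p = acceptance_probability(preference_distance(female, candidate), acceptance_scale)
        if float(rng.random()) >= p:
            return None
    return candidate


def form_pair(female: Agent, male: Agent, state) -> Pair:
    """Bind an unpaired, co-located, opposite-sex couple into a new pair."""
    if female.sex != Sex.FEMALE or male.sex != Sex.MALE:
        raise StructuralError("form_pair needs a female and a male, in that order")
    if female.pair_id is not None or male.pair_id is not None:
        raise StructuralError("both agents must be unpaired")
    if female.node != male.node:
        raise StructuralError("pair members must share a node (agents only see their own node)")
    pair = Pair(id=state.next_pair_id, female_id=female.id, male_id=male.id)
    state.next_pair_id += 1
    state.pairs[pair.id] = pair
    female.pair_id = pair.id
    male.pair_id = pair.id
    female.searching = False
    male.searching = False
    return pair


def dissolve_pair(state, pair_id: int) -> None:
    """Remove a pair; surviving members become unpaired."""
    pair = state.pairs.pop(pair_id)
    for aid in (pair.female_id, pair.male_id):
        agent = state.agents.get(aid)
        if agent is not None and agent.pair_id == pair_id:
            agent.pair_id = None


def age_and_dissolve_pairs(state, max_pair_age: Optional[int]) -> None:
    """Advance every pair's age by one step and dissolve expired/widowed pairs.

    A pair dissolves when its age exceeds ``max_pair_age`` or when a member
    has died.  With ``max_pair_age=None`` only widowed pairs are dissolved —
    the engine uses this in the ephemeral-pair regime, where dissolution is
    tied to the first brood instead of to age.
    """
    for pid in sorted(state.pairs):
        pair = state.pairs[pid]
        pair.pair_age += 1
        widowed = pair.female_id not in state.agents or pair.male_id not in state.agents
        if widowed or (max_pair_age is not None and pair.pair_age > max_pair_age):
            dissolve_pair(state, pid)


def reproduce(pair: Pair, state, rng) -> list[Agent]:
    """Create two offspring from a pair, funded by a parental resource transfer.

    Skipped (empty list) unless both members are ready.  The transferred amount
    is ``female_rep_cost * r_female + male_rep_cost * r_male``, split equally
    between the two children; the ledger total is unchanged.  Each offspring is
    built independently: intermediate recombination with probability
    ``rec_prob`` (otherwise a copy of a uniformly chosen parent's genotype),
    then whole-genotype mutation with probability ``mut_prob``; its ``x`` is
    clamped to the landscape domain.  Offspring are placed in the pair's node;
    under the default "balanced" rule the brood is one female plus one male.
    """
    cfg = state.config
    female = state.agents[pair.female_id]
    male = state.agents[pair.male_id]
    share = state.nominal_share
    if not (
        ready_for_reproduction(female, cfg.min_rep_res, share)
        and ready_for_reproduction(male, cfg.min_rep_res, share)
    ):
        return []

    from_female = cfg.female_rep_cost * female.resource
    from_male = cfg.male_rep_cost * male.resource
    female.resource -= from_female
    male.resource -= from_male
    endowment = (from_female + from_male) / 2.0

    params = state.variation
    spec = state.landscape
    children: list[Agent] = []
    for brood_index in range(2):
        if float(rng.random()) < params.rec_prob:
            g = genetics.recombine(female.genotype, male.genotype, rng)
        else:
            g = female.genotype if float(rng.random()) < 0.5 else male.genotype
        if float(rng.random()) < params.mut_prob:
            g = genetics.mutate(g, params, rng)
        x = landscapes.clamp(spec, g.x)
        g = Genotype(x=x, sigma=g.sigma)
        if cfg.offspring_sex_rule == "coin":
            sex = Sex.FEMALE if float(rng.random()) < 0.5 else Sex.MALE
        else:  # "balanced": one female + one male per brood
            sex = Sex.FEMALE if brood_index == 0 else Sex.MALE
        child = Agent(
            id=state.next_agent_id,
            sex=sex,
            genotype=g,
            resource=endowment,
            node=female.node,
            fitness=landscapes.evaluate(spec, x),
        )
        state.next_agent_id += 1
        state.agents[child.id] = child
        state.node_agents[child.node].add(child.id)
        children.append(child)
    return children
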