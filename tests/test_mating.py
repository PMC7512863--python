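import numpy as np
import pytest

import sympair as sp
from sympair import mating
from sympair.errors import DomainError, StructuralError
from sympair.genetics import Genotype
from sympair.mating import Agent, Sex


def make_agent(aid=0, sex=Sex.FEMALE, x=(0.0, 0.0), resource=5.0, node=0):
    return Agent(id=aid, sex=sex, genotype=Genotype(x=x, sigma=(0.1, 0.1)),
                 resource=resource, node=node)


class TestReadiness:
    def test_zero_resource_not_ready(self):
        a = make_agent(resource=0.0)
        assert not mating.ready_for_reproduction(a, 0.5, 5.0)

    def test_boundary_inclusive(self):
        assert mating.ready_for_reproduction(make_agent(resource=2.5), 0.5, 5.0)
        assert not mating.ready_for_reproduction(make_agent(resource=2.49), 0.5, 5.0)


class TestPreferenceDistance:
    def test_identical_genotypes(self):
        f = make_agent(0, Sex.FEMALE, x=(1.0, 2.0))
        m = make_agent(1, Sex.MALE, x=(1.0, 2.0))
        assert mating.preference_distance(f, m) == 0.0

    def test_three_four_five(self):
        f = make_agent(0, Sex.FEMALE, x=(0.0, 0.0))
        m = make_agent(1, Sex.MALE, x=(3.0, 4.0))
        assert mating.preference_distance(f, m) == pytest.approx(5.0)
        assert mating.preference_distance(f, m) == mating.preference_distance(f, m)

    def test_same_sex_rejected(self):
        with pytest.raises(StructuralError):
            mating.preference_distance(make_agent(0), make_agent(1))


class TestChoiceWeights:
    def test_single_candidate(self):
        assert mating.choice_weights([3.0]) == pytest.approx([1.0])

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            mating.choice_weights([])

    def test_strictly_decreasing_in_distance(self):
        w = mating.choice_weights([0.0, 0.5, 1.0, 4.0])
        assert all(a > b for a, b in zip(w, w[1:]))
        assert w.sum() == pytest.approx(1.0)
        assert w.min() > 0.0

    def test_selection_frequencies_match_weights(self, rng):
        """Empirical frequencies over 1e5 draws match the weights within 3 sigma."""
        f = make_agent(0, Sex.FEMALE, x=(0.0, 0.0))
        males = [make_agent(i, Sex.MALE, x=(d, 0.0)) for i, d in enumerate((0.0, 1.0, 3.0), start=1)]
        expected = mating.choice_weights([0.0, 1.0, 3.0])
        n = 100_000
        counts = np.zeros(3)
        for _ in range(n):
            chosen = mating.choose_partner(f, males, rng, sexual_selection_on=True)
            counts[chosen.id - 1] += 1
        for p, c in zip(expected, counts):
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(c - n * p) < 3 * sigma


class TestChoosePartner:
    def test_empty_candidates(self, rng):
        f = make_agent(0, Sex.FEMALE)
        assert mating.choose_partner(f, [], rng, True) is None
        assert mating.choose_partner(f, [], rng, False) is None

    def test_single_candidate_both_modes(self, rng):
        f = make_agent(0, Sex.FEMALE)
        m = make_agent(1, Sex.MALE, x=(2.0, 2.0))
        assert mating.choose_partner(f, [m], rng, True) is m
        assert mating.choose_partner(f, [m], rng, False) is m

    def test_uniform_when_selection_off(self, rng):
        f = make_agent(0, Sex.FEMALE, x=(0.0, 0.0))
        males = [make_agent(1, Sex.MALE, x=(0.0, 0.0)), make_agent(2, Sex.MALE, x=(5.0, 5.0))]
        n = 100_000
        hits = sum(
            mating.choose_partner(f, males, rng, sexual_selection_on=False).id == 1
            for _ in range(n)
        )
        sigma = np.sqrt(n * 0.25)
        assert abs(hits - n / 2) < 3 * sigma

    def test_identical_males_reduce_to_uniform_weights(self):
        """With genetically identical males, sexual selection is uniform choice."""
        f = make_agent(0, Sex.FEMALE, x=(1.0, 1.0))
        males = [make_agent(i, Sex.MALE, x=(0.5, 0.5)) for i in range(1, 5)]
        d = [mating.preference_distance(f, m) for m in males]
        assert mating.choice_weights(d) == pytest.approx([0.25] * 4)


@pytest.fixture
def small_state():
    cfg = sp.SimulationConfig(
        initial_population=8, total_resource=40.0, steps=0, seed=11,
        grid_rows=4, grid_cols=4, mut_prob=0.0, rec_prob=1.0,
    )
    return sp.initialize(cfg)


def co_located_couple(state):
    agents = list(state.agents.values())
    female = next(a for a in agents if a.sex == Sex.FEMALE)
    male = next(a for a in agents if a.sex == Sex.MALE)
    state.node_agents[male.node].discard(male.id)
    male.node = female.node
    state.node_agents[female.node].add(male.id)
    return female, male


class TestPairLifecycle:
    def test_form_pair_links_members(self, small_state):
        f, m = co_located_couple(small_state)
        pair = mating.form_pair(f, m, small_state)
        assert f.pair_id == pair.id and m.pair_id == pair.id
        assert small_state.pairs[pair.id].pair_age == 0

    def test_paired_male_rejected(self, small_state):
        f, m = co_located_couple(small_state)
        mating.form_pair(f, m, small_state)
        other = next(
            a for a in small_state.agents.values()
            if a.sex == Sex.FEMALE and a.pair_id is None
        )
        other.node = m.node
        with pytest.raises(StructuralError):
            mating.form_pair(other, m, small_state)

    def test_cross_node_pair_rejected(self, small_state):
        agents = list(small_state.agents.values())
        f = next(a for a in agents if a.sex == Sex.FEMALE)
        m = next(a for a in agents if a.sex == Sex.MALE)
        m.node = [n for n in small_state.graph.node_ids if n != f.node][0]
        with pytest.raises(StructuralError):
            mating.form_pair(f, m, small_state)

    def test_aging_dissolves_expired_pairs(self, small_state):
        f, m = co_located_couple(small_state)
        pair = mating.form_pair(f, m, small_state)
        mating.age_and_dissolve_pairs(small_state, max_pair_age=2)
        mating.age_and_dissolve_pairs(small_state, max_pair_age=2)
        assert pair.id in small_state.pairs
        mating.age_and_dissolve_pairs(small_state, max_pair_age=2)
        assert pair.id not in small_state.pairs
        assert f.pair_id is None and m.pair_id is None

    def test_widowed_pair_dissolved(self, small_state):
        f, m = co_located_couple(small_state)
        pair = mating.form_pair(f, m, small_state)
        small_state.node_agents[m.node].discard(m.id)
        del small_state.agents[m.id]
        mating.age_and_dissolve_pairs(small_state, max_pair_age=100)
        assert pair.id not in small_state.pairs
        assert f.pair_id is None


class TestReproduce:
    def test_resource_transfer_arithmetic(self, small_state):
        f, m = co_located_couple(small_state)
        f.resource = m.resource = 1.0
        # make both ready against the tiny nominal share
        small_state.config = small_state.config.with_overrides(min_rep_res=0.1)
        pair = mating.form_pair(f, m, small_state)
        total_before = small_state.ledger.total()
        children = mating.reproduce(pair, small_state, np.random.default_rng(0))
        assert len(children) == 2
        assert f.resource == pytest.approx(0.6)
        assert m.resource == pytest.approx(0.8)
        assert children[0].resource == pytest.approx(0.3)
        assert children[1].resource == pytest.approx(0.3)
        assert small_state.ledger.total() == pytest.approx(total_before, rel=1e-12)

    def test_not_ready_pair_skipped(self, small_state):
        f, m = co_located_couple(small_state)
        f.resource = 0.01
        pair = mating.form_pair(f, m, small_state)
        assert mating.reproduce(pair, small_state, np.random.default_rng(0)) == []

    def test_identical_parents_without_mutation_breed_true(self, small_state):
        f, m = co_located_couple(small_state)
        g = Genotype(x=(0.5, -0.5), sigma=(0.1, 0.1))
        f.genotype = m.genotype = g
        pair = mating.form_pair(f, m, small_state)
        children = mating.reproduce(pair, small_state, np.random.default_rng(1))
        assert all(c.genotype.x == pytest.approx(g.x) for c in children)

    def test_offspring_balanced_sexes_and_in_domain(self, small_state):
        f, m = co_located_couple(small_state)
        small_state.config = small_state.config.with_overrides(mut_prob=1.0)
        pair = mating.form_pair(f, m, small_state)
        rng = np.random.default_rng(2)
        spec = small_state.landscape
        for _ in range(50):
            f.resource = m.resource = 5.0
            children = mating.reproduce(pair, small_state, rng)
            assert {c.sex for c in children} == {Sex.FEMALE, Sex.MALE}
            for c in children:
                assert spec.contains(c.genotype.x)
                assert c.node == f.node

    def test_female_outflow_exceeds_male_outflow(self, small_state):
        f, m = co_located_couple(small_state)
        f.resource, m.resource = 4.0, 3.0
        pair = mating.form_pair(f, m, small_state)
        mating.reproduce(pair, small_state, np.random.default_rng(3))
        assert (4.0 - f.resource) > (3.0 - m.resource)
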