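"""Memory activation, retrieval, blending and choice of the IBL agent."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iblgames.ibl import (
    AgentParams,
    IBLAgent,
    Instance,
    Memory,
    activation,
    blended_value,
    choose,
    retrieval_probabilities,
    update_memory,
)


def brute_force_activation(occurrences, t, d, sigma, gamma):
    """Independent recomputation of the activation formula."""
    total = sum((t - tp) ** (-d) for tp in occurrences)
    noise = sigma * math.log((1 - gamma) / gamma) if sigma else 0.0
    return math.log(total) + noise


class TestActivation:
    @pytest.mark.parametrize(
        "occurrences,t,d,expected",
        [
            ([1], 2, 0.5, 0.0),
            ([1, 2], 3, 1.0, math.log(1.5)),
            ([1], 5, 0.5, math.log(4 ** -0.5)),
        ],
    )
    def test_noise_free_values(self, occurrences, t, d, expected):
        inst = Instance(1, 5.0, occurrences)
        params = AgentParams(d=d, sigma=0.0)
        assert activation(inst, t, params, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_future_reference_rejected(self):
        inst = Instance(1, 5.0, [3])
        with pytest.raises(ValueError, match="backwards"):
            activation(inst, 3, AgentParams(), 0.5)

    @pytest.mark.parametrize("gamma", [0.0, 1.0])
    def test_endpoint_noise_draw_rejected(self, gamma):
        inst = Instance(1, 5.0, [1])
        with pytest.raises(ValueError):
            activation(inst, 2, AgentParams(), gamma)

    def test_matches_brute_force_on_random_memories(self, rng):
        for _ in range(200):
            n_occ = int(rng.integers(1, 6))
            occ = sorted(rng.choice(np.arange(1, 20), size=n_occ, replace=False))
            t = int(occ[-1] + rng.integers(1, 10))
            d = float(rng.uniform(0, 30))
            sigma = float(rng.uniform(0, 30))
            gamma = float(rng.uniform(0.01, 0.99))
            inst = Instance(0, -10.0, [int(o) for o in occ])
            got = activation(inst, t, AgentParams(d=d, sigma=sigma), gamma)
            want = brute_force_activation(occ, t, d, sigma, gamma)
            assert got == pytest.approx(want, abs=1e-12)

    def test_extra_occurrence_raises_activation(self):
        # frequency monotonicity at sigma=0
        params = AgentParams(d=0.5, sigma=0.0)
        base = activation(Instance(1, 5.0, [2, 5]), 10, params, 0.5)
        more = activation(Instance(1, 5.0, [2, 5, 7]), 10, params, 0.5)
        assert more > base


class TestRetrievalProbabilities:
    def test_single_instance_gets_all_mass(self):
        assert retrieval_probabilities([1.7], tau=0.3).tolist() == [1.0]

    def test_equal_activations_split_evenly(self):
        probs = retrieval_probabilities([0.4, 0.4], tau=0.5)
        assert probs.tolist() == [0.5, 0.5]

    def test_closed_form_softmax(self):
        probs = retrieval_probabilities([0.0, math.log(2)], tau=1.0)
        assert probs == pytest.approx([1 / 3, 2 / 3], abs=1e-12)

    def test_zero_temperature_is_argmax_with_tie_split(self):
        probs = retrieval_probabilities([1.0, 3.0, 3.0], tau=0.0)
        assert probs.tolist() == [0.0, 0.5, 0.5]

    @given(
        acts=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        tau=st.floats(0.01, 40),
    )
    @settings(deadline=None)
    def test_normalization_and_order(self, acts, tau):
        probs = retrieval_probabilities(acts, tau)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        order = np.argsort(acts, kind="stable")
        assert (np.diff(probs[order]) >= -1e-15).all()


def two_instance_memory():
    mem = Memory()
    mem.add(1, 5.0, 1)
    mem.add(1, -10.0, 2)
    return mem


class TestBlendedValue:
    def test_single_instance_blend_is_its_outcome(self):
        mem = Memory()
        mem.add(1, 5.0, 1)
        v = blended_value(1, mem, 4, AgentParams(sigma=0.0), np.random.default_rng(0))
        assert v == 5.0

    def test_equal_weight_blend(self):
        # equal activations: same lag structure, no noise
        mem = Memory()
        mem.add(1, 5.0, 1)
        mem.add(1, -10.0, 1)
        v = blended_value(1, mem, 2, AgentParams(d=0.5, sigma=0.0), np.random.default_rng(0))
        assert v == pytest.approx(-2.5, abs=1e-12)

    def test_weighted_blend_closed_form(self):
        # retrieval probabilities (0.75, 0.25) on outcomes (+5, -10)
        assert 0.75 * 5 + 0.25 * (-10) == pytest.approx(1.25)
        probs = np.array([0.75, 0.25])
        assert float(probs @ [5.0, -10.0]) == pytest.approx(1.25, abs=1e-12)

    def test_matches_brute_force_with_shared_draws(self, eqp):
        params = AgentParams(d=3.0, sigma=1.2)
        mem = Memory()
        mem.add(1, 5.0, 1)
        mem.add(1, -10.0, 2)
        mem.add(1, 5.0, 3)
        t = 7
        v = blended_value(1, mem, t, params, np.random.default_rng(99))
        draws = np.random.default_rng(99).random(2)  # two instances under alt 1
        insts = mem.instances(1)
        acts = [
            brute_force_activation(i.occurrences, t, params.d, params.sigma, g)
            for i, g in zip(insts, draws)
        ]
        ws = np.exp((np.array(acts) - max(acts)) / params.tau)
        want = float(ws @ [i.outcome for i in insts] / ws.sum())
        assert v == pytest.approx(want, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_blend_is_convex_combination(self, seed):
        rng = np.random.default_rng(seed)
        mem = Memory()
        outcomes = rng.integers(-50, 51, size=4)
        for t, x in enumerate(outcomes, start=1):
            mem.add(1, float(x), t)
        v = blended_value(1, mem, 6, AgentParams(d=1.0, sigma=5.0), rng)
        assert min(outcomes) - 1e-12 <= v <= max(outcomes) + 1e-12

    def test_high_decay_converges_to_most_recent_outcome(self):
        mem = Memory()
        mem.add(1, 5.0, 1)
        mem.add(1, 5.0, 2)
        mem.add(1, -10.0, 9)
        v = blended_value(1, mem, 10, AgentParams(d=30.0, sigma=0.0), np.random.default_rng(0))
        assert v == pytest.approx(-10.0, abs=1e-6)


class TestChoice:
    def test_argmax_choice(self):
        mem = Memory()
        mem.add(1, 5.0, 1)
        mem.add(0, 0.0, 2)
        picked = choose(mem, 3, AgentParams(sigma=0.0), np.random.default_rng(0))
        assert picked == 1

    def test_exact_ties_split_evenly(self):
        # both alternatives hold one instance with the same outcome and lag
        params = AgentParams(d=0.5, sigma=0.0)
        rng = np.random.default_rng(42)
        picks = []
        for _ in range(10_000):
            mem = Memory()
            mem.add(0, 5.0, 0)
            mem.add(1, 5.0, 0)
            picks.append(choose(mem, 1, params, rng))
        assert np.mean(picks) == pytest.approx(0.5, abs=0.02)

    def test_fresh_agent_first_choice_uniform_across_seeds(self, eqp):
        firsts = [
            IBLAgent(
                AgentParams(sigma=0.0), np.random.default_rng(s), prepopulation_value=10.0
            ).choose(1)
            for s in range(2000)
        ]
        assert np.mean(firsts) == pytest.approx(0.5, abs=0.05)

    def test_agent_fast_path_matches_functional_path(self):
        # the agent's inlined choose() must consume the same draws and
        # produce the same blends as blended_value() per alternative
        params = AgentParams(d=2.0, sigma=4.0)
        agent = IBLAgent(params, np.random.default_rng(7), prepopulation_value=10.0)
        agent.learn(1, 5.0, 1)
        agent.learn(0, 0.0, 2)
        agent.learn(1, -10.0, 3)
        agent.choose(4)
        blends_fast = dict(agent.last_blends)

        mem = Memory()
        mem.add(0, 10.0, 0)
        mem.add(1, 10.0, 0)
        mem.add(1, 5.0, 1)
        mem.add(0, 0.0, 2)
        mem.add(1, -10.0, 3)
        rng = np.random.default_rng(7)  # no draws consumed before trial 4
        blends_func = {alt: blended_value(alt, mem, 4, params, rng) for alt in (0, 1)}
        for alt in (0, 1):
            assert blends_fast[alt] == pytest.approx(blends_func[alt], abs=1e-12)


class TestMemory:
    def test_new_instance_then_reinforcement(self):
        mem = Memory()
        update_memory(mem, 1, 5.0, 1)
        update_memory(mem, 1, 5.0, 3)
        (inst,) = mem.instances(1)
        assert inst.occurrences == [1, 3]

    def test_distinct_outcomes_make_distinct_instances(self):
        mem = Memory()
        mem.add(1, 5.0, 1)
        mem.add(1, -10.0, 2)
        assert len(mem.instances(1)) == 2

    def test_non_monotone_trial_rejected(self):
        mem = Memory()
        mem.add(1, 5.0, 3)
        with pytest.raises(ValueError):
            mem.add(0, 0.0, 2)

    def test_serialization_round_trip(self):
        mem = two_instance_memory()
        clone = Memory.from_dict(mem.to_dict())
        assert clone.to_dict() == mem.to_dict()
        assert clone.last_t == mem.last_t

    def test_only_own_outcome_stored_by_agent(self, eqp):
        agent = IBLAgent(AgentParams(), np.random.default_rng(0), prepopulation_value=10.0)
        agent.learn(1, -10.0, 1)
        # two prepopulated + one experienced instance, nothing else
        assert len(agent.memory) == 3


class TestAgentParams:
    def test_tau_rules(self):
        assert AgentParams(sigma=0.25).tau == pytest.approx(0.25 * math.sqrt(2))
        assert AgentParams(sigma=0.25, tau_rule="times2").tau == pytest.approx(0.5)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            AgentParams(d=-1.0)
        with pytest.raises(ValueError):
            AgentParams(sigma=-0.1)
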