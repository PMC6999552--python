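"""Instance-based learning agent: memory, activation, blending, choice.

The agent stores its experience as *instances* -- (alternative, outcome)
pairs together with the trials at which that outcome occurred.  On every
trial it computes a noisy memory activation for each instance, converts
activations to retrieval probabilities with a Boltzmann (softmax) rule,
blends each alternative's stored outcomes by those probabilities, and
picks the alternative with the highest blended value.

Activation of instance *i* at trial *t*:

    A_i = ln( sum over past occurrences t_p of (t - t_p)^(-d) )
          + sigma * ln((1 - gamma) / gamma),      gamma ~ Uniform(0, 1)

where ``d`` is the memory-decay parameter (higher d = stronger recency)
and ``sigma`` scales the logistic activation noise.  Retrieval
probability of instance i within its alternative is
``exp(A_i / tau) / sum_k exp(A_k / tau)`` with temperature
``tau = sigma * sqrt(2)`` (a ``times2`` variant is available).  The
blended value of an alternative is the retrieval-probability-weighted
mean of its stored outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

TAU_RULES = ("sqrt2", "times2")


@dataclass
class AgentParams:
    """Free parameters of the IBL agent.

    Parameters
    ----------
    d
        Memory decay (unitless, >= 0).  ACT-R default 0.5; calibrated
        values may run up to 30.
    sigma
        Activation-noise scale (unitless, >= 0).  ACT-R default 0.25.
    prepopulation_value
        Outcome (points) of the synthetic instance seeded for each
        alternative before play.  ``None`` means "use the largest
        absolute payoff the agent's role can experience" (optimistic
        prepopulation, which drives early exploration).
    tau_rule
        How the Boltzmann temperature is derived from sigma:
        ``"sqrt2"`` (tau = sigma*sqrt(2), the standard form) or
        ``"times2"`` (tau = 2*sigma).
    """

    d: float = 0.5
    sigma: float = 0.25
    prepopulation_value: Optional[float] = None
    tau_rule: str = "sqrt2"

    def __post_init__(self) -> None:
        if self.d < 0 or self.sigma < 0:
            raise ValueError("d and sigma must be non-negative")
        if self.tau_rule not in TAU_RULES:
            raise ValueError(f"tau_rule must be one of {TAU_RULES}")

    @property
    def tau(self) -> float:
        if self.tau_rule == "sqrt2":
            return self.sigma * math.sqrt(2.0)
        return self.sigma * 2.0


@dataclass
class Instance:
    """One memory trace: an alternative, an outcome, and when it occurred.

    ``occurrences`` holds the (1-based) trial indices at which this
    (alternative, outcome) pair was experienced, in strictly increasing
    order; index 0 is reserved for prepopulated instances.
    """

    alternative: int
    outcome: float
    occurrences: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.occurrences:
            raise ValueError("an instance needs at least one occurrence")
        if any(b <= a for a, b in zip(self.occurrences, self.occurrences[1:])):
            raise ValueError("occurrences must be strictly increasing")


def activation(
    instance: Instance, t: int, params: AgentParams, noise_draw: float
) -> float:
    """Activation of one instance at trial ``t`` given a uniform noise draw.

    Deterministic given ``noise_draw``; the caller owns the randomness
    (and must resample draws that land exactly on 0 or 1, where the
    logistic noise term is undefined).
    """
    if instance.occurrences[-1] >= t:
        raise ValueError(
            f"instance occurred at trial {instance.occurrences[-1]} "
            f">= current trial {t}; activation only looks backwards"
        )
    if not 0.0 < noise_draw < 1.0:
        raise ValueError("noise_draw must lie strictly inside (0, 1)")
    s = 0.0
    for tp in instance.occurrences:
        s += (t - tp) ** (-params.d)
    base = math.log(s)
    if params.sigma == 0.0:
        return base
    return base + params.sigma * math.log((1.0 - noise_draw) / noise_draw)


def retrieval_probabilities(activations, tau: float) -> np.ndarray:
    """Boltzmann retrieval probabilities over one alternative's instances.

    With ``tau == 0`` the softmax limit is used: all mass on the
    maximal activation, split uniformly over exact ties.
    """
    acts = np.asarray(activations, dtype=float)
    if acts.size == 0:
        raise ValueError("need at least one activation")
    if tau == 0.0:
        top = acts == acts.max()
        return top / top.sum()
    z = (acts - acts.max()) / tau
    w = np.exp(z)
    return w / w.sum()


class Memory:
    """Instance store for one agent, keyed by (alternative, outcome)."""

    def __init__(self) -> None:
        self._store: Dict[Tuple[int, float], Instance] = {}
        self._by_alt: Dict[int, List[Instance]] = {}
        self.last_t: int = 0

    def add(self, alternative: int, outcome: float, t: int) -> None:
        """Record that ``outcome`` followed ``alternative`` at trial ``t``.

        Reinforces the existing instance if the (alternative, outcome)
        pair was seen before, otherwise creates a new one.  Trials must
        be non-decreasing overall and strictly increasing per instance.
        """
        if t < self.last_t:
            raise ValueError(f"trial index went backwards: {t} < {self.last_t}")
        key = (alternative, float(outcome))
        inst = self._store.get(key)
        if inst is None:
            inst = Instance(alternative, float(outcome), [t])
            self._store[key] = inst
            self._by_alt.setdefault(alternative, []).append(inst)
        else:
            if t <= inst.occurrences[-1]:
                raise ValueError("duplicate occurrence index for an instance")
            inst.occurrences.append(t)
        self.last_t = t

    def instances(self, alternative: int) -> List[Instance]:
        return list(self._by_alt.get(alternative, []))

    def __len__(self) -> int:
        return len(self._store)

    def to_dict(self) -> dict:
        return {
            "last_t": self.last_t,
            "instances": [
                {
                    "alternative": inst.alternative,
                    "outcome": inst.outcome,
                    "occurrences": list(inst.occurrences),
                }
                for inst in self._store.values()
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Memory":
        mem = cls()
        for rec in data["instances"]:
            inst = Instance(
                rec["alternative"], float(rec["outcome"]), list(rec["occurrences"])
            )
            mem._store[(inst.alternative, inst.outcome)] = inst
            mem._by_alt.setdefault(inst.alternative, []).append(inst)
        mem.last_t = data["last_t"]
        return mem


def _draw_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform draws strictly inside (0, 1); endpoint draws are resampled."""
    g = rng.random(n)
    while True:
        bad = (g <= 0.0) | (g >= 1.0)
        if not bad.any():
            return g
        g[bad] = rng.random(int(bad.sum()))


def blended_value(
    alternative: int,
    memory: Memory,
    t: int,
    params: AgentParams,
    rng: np.random.Generator,
) -> float:
    """Retrieval-probability-weighted mean outcome of one alternative.

    Draws fresh activation noise for every instance of the alternative,
    so repeated calls with the same ``rng`` state differ; within one
    trial the agent evaluates each alternative exactly once.
    """
    insts = memory.instances(alternative)
    if not insts:
        raise ValueError(f"alternative {alternative} has no instances in memory")
    draws = _draw_noise(rng, len(insts))
    acts = [activation(inst, t, params, g) for inst, g in zip(insts, draws)]
    probs = retrieval_probabilities(acts, params.tau)
    return float(np.dot(probs, [inst.outcome for inst in insts]))


def update_memory(memory: Memory, action: int, outcome: float, t: int) -> Memory:
    """Store the chosen action's experienced outcome at trial ``t``."""
    memory.add(action, outcome, t)
    return memory


class IBLAgent:
    """A player that chooses between two alternatives by blended value.

    Memory is prepopulated with one synthetic instance per alternative at
    pseudo-trial 0, so the first real choice (t=1) is defined and lags
    stay >= 1.  Only the agent's own chosen action and experienced
    outcome are stored -- foregone and opponent payoffs are not learned.
    """

    def __init__(
        self,
        params: AgentParams,
        rng: np.random.Generator,
        prepopulation_value: float,
        alternatives: Tuple[int, int] = (0, 1),
    ) -> None:
        self.params = params
        self.rng = rng
        self.alternatives = alternatives
        self.memory = Memory()
        for alt in alternatives:
            self.memory.add(alt, prepopulation_value, 0)
        self.last_blends: Dict[int, float] = {}

    def choose(self, t: int) -> int:
        """Pick the alternative with the highest blended value at trial ``t``.

        Exact ties are broken uniformly at random.  This is an inlined
        (loop-free-of-numpy) equivalent of calling
        :func:`blended_value` once per alternative with the agent's rng.
        """
        params = self.params
        d, sigma, tau = params.d, params.sigma, params.tau
        rng_random = self.rng.random
        by_alt = self.memory._by_alt
        blends: Dict[int, float] = {}
        for alt in self.alternatives:
            insts = by_alt.get(alt)
            if not insts:
                raise ValueError(f"alternative {alt} has no instances in memory")
            draws = rng_random(len(insts))
            acts = []
            for inst, g in zip(insts, draws):
                while not 0.0 < g < 1.0:
                    g = rng_random()
                s = 0.0
                for tp in inst.occurrences:
                    s += (t - tp) ** (-d)
                a = math.log(s)
                if sigma:
                    a += sigma * math.log((1.0 - g) / g)
                acts.append(a)
            if tau == 0.0:
                m = max(acts)
                ws = [1.0 if a == m else 0.0 for a in acts]
            else:
                m = max(acts)
                ws = [math.exp((a - m) / tau) for a in acts]
            tot = sum(ws)
            blends[alt] = (
                sum(w * inst.outcome for w, inst in zip(ws, insts)) / tot
            )
        self.last_blends = blends
        best = max(blends.values())
        top = [alt for alt, v in blends.items() if v == best]
        if len(top) == 1:
            return top[0]
        return top[int(self.rng.integers(len(top)))]

    def learn(self, action: int, outcome: float, t: int) -> None:
        update_memory(self.memory, action, outcome, t)


def choose(
    memory: Memory, t: int, params: AgentParams, rng: np.random.Generator
) -> int:
    """Functional form of the choice rule over alternatives {0, 1}."""
    blends = {
        alt: blended_value(alt, memory, t, params, rng) for alt in (0, 1)
    }
    best = max(blends.values())
    top = [alt for alt, v in blends.items() if v == best]
    if len(top) == 1:
        return top[0]
    return top[int(rng.integers(len(top)))]
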