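"""Repeated-game simulation: IBL pairs and IBL-vs-Nash-bot episodes.

A *pair* is one adversary and one defender playing ``n_trials``
simultaneous rounds of a payoff condition.  A *condition run* replicates
independent pairs and aggregates their binary actions into a per-trial
proportion series (the quantity model fits are scored on).  Seeding uses
``numpy.random.SeedSequence`` spawning, so every pair has an independent
substream and adding pairs never perturbs earlier ones.

Trial records are kept as a pandas ``DataFrame`` with columns
``condition, pair_id, trial, adv_action, def_action, adv_payoff,
def_payoff`` and can round-trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .game import PayoffMatrix, resolve_outcome
from .ibl import AgentParams, IBLAgent

RECORD_COLUMNS = [
    "condition",
    "pair_id",
    "trial",
    "adv_action",
    "def_action",
    "adv_payoff",
    "def_payoff",
]

#: Starting score of every player; bookkeeping only, never enters choice.
DEFAULT_ENDOWMENT = 2500

SeedLike = Union[int, np.random.SeedSequence]


def _seed_sequence(seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class ProportionSeries:
    """Per-trial mean attack and defend proportions across pairs."""

    attack: np.ndarray
    defend: np.ndarray

    def __post_init__(self) -> None:
        self.attack = np.asarray(self.attack, dtype=float)
        self.defend = np.asarray(self.defend, dtype=float)
        if self.attack.shape != self.defend.shape or self.attack.ndim != 1:
            raise ValueError("attack and defend series must be 1-D and equal length")
        for arr in (self.attack, self.defend):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("proportions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.attack)

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "ProportionSeries":
        if records.empty:
            raise ValueError("cannot build a proportion series from no records")
        by_trial = records.groupby("trial")[["adv_action", "def_action"]].mean()
        by_trial = by_trial.sort_index()
        return cls(by_trial["adv_action"].to_numpy(), by_trial["def_action"].to_numpy())


def _make_agent(
    params: AgentParams, matrix: PayoffMatrix, role: str, rng: np.random.Generator
) -> IBLAgent:
    prepop = params.prepopulation_value
    if prepop is None:
        prepop = matrix.max_magnitude(role)
    return IBLAgent(params, rng, prepopulation_value=prepop)


def _play_trials(
    matrix: PayoffMatrix,
    adv_choose,
    def_choose,
    adv_learn,
    def_learn,
    n_trials: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    a_act = np.empty(n_trials, dtype=np.int64)
    d_act = np.empty(n_trials, dtype=np.int64)
    a_pay = np.empty(n_trials, dtype=np.int64)
    d_pay = np.empty(n_trials, dtype=np.int64)
    adv_map = matrix.adv_payoff
    def_map = matrix.def_payoff
    for i in range(n_trials):
        t = i + 1
        a = adv_choose(t)
        d = def_choose(t)
        key = (a, d)
        pa, pd_ = adv_map[key], def_map[key]
        if adv_learn is not None:
            adv_learn(a, pa, t)
        if def_learn is not None:
            def_learn(d, pd_, t)
        a_act[i], d_act[i], a_pay[i], d_pay[i] = a, d, pa, pd_
    return a_act, d_act, a_pay, d_pay


def _records_frame(matrix, pair_ids, trials, a_act, d_act, a_pay, d_pay) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": pd.Series(
                np.repeat(matrix.condition, len(trials)), dtype="string"
            ),
            "pair_id": np.asarray(pair_ids, dtype=np.int64),
            "trial": np.asarray(trials, dtype=np.int64),
            "adv_action": a_act,
            "def_action": d_act,
            "adv_payoff": a_pay,
            "def_payoff": d_pay,
        }
    )


def _pair_arrays(
    matrix: PayoffMatrix,
    adv_params: AgentParams,
    def_params: AgentParams,
    n_trials: int,
    seed: SeedLike,
):
    ss = _seed_sequence(seed)
    adv_ss, def_ss = ss.spawn(2)
    adv = _make_agent(adv_params, matrix, "adversary", np.random.default_rng(adv_ss))
    dfn = _make_agent(def_params, matrix, "defender", np.random.default_rng(def_ss))
    return _play_trials(matrix, adv.choose, dfn.choose, adv.learn, dfn.learn, n_trials)


def _stack_pairs(matrix: PayoffMatrix, per_pair, n_trials: int) -> pd.DataFrame:
    n_pairs = len(per_pair)
    trials = np.tile(np.arange(1, n_trials + 1), n_pairs)
    pair_ids = np.repeat(np.arange(n_pairs), n_trials)
    cols = [np.concatenate([arrs[i] for arrs in per_pair]) for i in range(4)]
    return _records_frame(matrix, pair_ids, trials, *cols)


def run_pair(
    matrix: PayoffMatrix,
    adv_params: AgentParams,
    def_params: AgentParams,
    n_trials: int,
    seed: SeedLike,
    pair_id: int = 0,
) -> pd.DataFrame:
    """Simulate one IBL adversary vs. one IBL defender for ``n_trials``.

    Both agents choose simultaneously each trial; each learns only its
    own realized outcome.  Fully reproducible from ``seed``.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    arrays = _pair_arrays(matrix, adv_params, def_params, n_trials, seed)
    trials = np.arange(1, n_trials + 1)
    return _records_frame(matrix, np.full(n_trials, pair_id), trials, *arrays)


def run_condition(
    matrix: PayoffMatrix,
    adv_params: AgentParams,
    def_params: AgentParams,
    n_pairs: int = 25,
    n_trials: int = 50,
    seed: SeedLike = 0,
) -> Tuple[pd.DataFrame, ProportionSeries]:
    """Replicate ``n_pairs`` independent IBL-vs-IBL pairs of one condition."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    ss = _seed_sequence(seed)
    per_pair = [
        _pair_arrays(matrix, adv_params, def_params, n_trials, child)
        for child in ss.spawn(n_pairs)
    ]
    records = _stack_pairs(matrix, per_pair, n_trials)
    return records, ProportionSeries.from_records(records)


def simulate_series(
    matrix: PayoffMatrix,
    adv_params: AgentParams,
    def_params: AgentParams,
    n_pairs: int = 25,
    n_trials: int = 50,
    seed: SeedLike = 0,
) -> ProportionSeries:
    """Proportion series of a condition run without materializing records.

    Identical seeding and trajectories to :func:`run_condition`; used
    where only the per-trial means are needed (e.g. inside calibration
    fitness evaluations).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    ss = _seed_sequence(seed)
    a_sum = np.zeros(n_trials)
    d_sum = np.zeros(n_trials)
    for child in ss.spawn(n_pairs):
        a_act, d_act, _, _ = _pair_arrays(matrix, adv_params, def_params, n_trials, child)
        a_sum += a_act
        d_sum += d_act
    return ProportionSeries(a_sum / n_pairs, d_sum / n_pairs)


def run_vs_nash_bot(
    matrix: PayoffMatrix,
    role: str,
    params: AgentParams,
    bot_mix: float,
    n_pairs: int = 25,
    n_trials: int = 50,
    seed: SeedLike = 0,
) -> Tuple[pd.DataFrame, ProportionSeries]:
    """IBL agent in ``role`` against a memoryless Bernoulli opponent.

    The bot plays its action i.i.d. with probability ``bot_mix`` every
    trial (a "Nash bot" when the mix is the equilibrium probability);
    the IBL agent learns from its own outcomes as usual.
    """
    if role not in ("adversary", "defender"):
        raise ValueError("role must be 'adversary' or 'defender'")
    if not 0.0 <= bot_mix <= 1.0:
        raise ValueError("bot_mix must lie in [0, 1]")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    ss = _seed_sequence(seed)
    per_pair = []
    for child in ss.spawn(n_pairs):
        agent_ss, bot_ss = child.spawn(2)
        agent = _make_agent(params, matrix, role, np.random.default_rng(agent_ss))
        bot_rng = np.random.default_rng(bot_ss)
        bot_choose = lambda t: int(bot_rng.random() < bot_mix)
        if role == "adversary":
            arrays = _play_trials(
                matrix, agent.choose, bot_choose, agent.learn, None, n_trials
            )
        else:
            arrays = _play_trials(
                matrix, bot_choose, agent.choose, None, agent.learn, n_trials
            )
        per_pair.append(arrays)
    records = _stack_pairs(matrix, per_pair, n_trials)
    return records, ProportionSeries.from_records(records)


def mean_proportions(records: pd.DataFrame) -> Tuple[float, float]:
    """Grand mean attack and defend proportions over all pairs and trials."""
    if records.empty:
        raise ValueError("no records to average")
    return float(records["adv_action"].mean()), float(records["def_action"].mean())


def cumulative_scores(
    records: pd.DataFrame, endowment: float = DEFAULT_ENDOWMENT
) -> pd.DataFrame:
    """Running total score per pair and role, starting from the endowment."""
    out = records[["condition", "pair_id", "trial"]].copy()
    grouped = records.groupby("pair_id", sort=False)
    out["adv_total"] = endowment + grouped["adv_payoff"].cumsum()
    out["def_total"] = endowment + grouped["def_payoff"].cumsum()
    return out


def write_records(records: pd.DataFrame, path) -> None:
    """Write trial records as CSV with the canonical column order."""
    records[RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read trial records written by :func:`write_records`."""
    df = pd.read_csv(
        path,
        dtype={
            "condition": "string",
            "pair_id": np.int64,
            "trial": np.int64,
            "adv_action": np.int64,
            "def_action": np.int64,
            "adv_payoff": np.int64,
            "def_payoff": np.int64,
        },
    )
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file is missing columns: {sorted(missing)}")
    return df[RECORD_COLUMNS]
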