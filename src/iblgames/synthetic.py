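"""Pseudo-participant trial data with known statistical structure.

The study design this emulates is 25 pairs playing 50 repeated trials
per condition, with one binary action per role per trial.  Because the
original behavioral records are not redistributable, every downstream
stage (statistics, calibration, generalization) is exercised on
generated data whose ground truth is known:

``ibl``
    pairs of instance-based-learning agents with set (d, sigma) -- the
    data-generating process the calibration machinery assumes;
``nash_bernoulli``
    both roles play their equilibrium mix i.i.d. (defaults taken from
    the analytic solver);
``biased_bernoulli``
    i.i.d. play at arbitrary fixed rates;
``sticky``
    repeat the previous action with a fixed stay-probability, a
    non-IBL serial-dependence foil.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult, GAConfig, calibrate_ga, fitness
from .engine import ProportionSeries, _records_frame, _seed_sequence, run_condition
from .game import PayoffMatrix, make_condition, solve_nash
from .ibl import AgentParams

KINDS = ("ibl", "nash_bernoulli", "biased_bernoulli", "sticky")


@dataclass
class GeneratorSpec:
    """What to generate: agent kind, per-role parameters, and design size.

    ``p_attack``/``q_defend`` parameterize the Bernoulli kinds (for
    ``nash_bernoulli`` they default to the condition's equilibrium);
    ``adv_params``/``def_params`` parameterize the ``ibl`` kind;
    ``stay_prob`` is the sticky generator's probability of repeating the
    previous action.
    """

    kind: str
    condition: str = "EQP"
    n_pairs: int = 25
    n_trials: int = 50
    seed: int = 0
    adv_params: AgentParams = field(default_factory=AgentParams)
    def_params: AgentParams = field(default_factory=AgentParams)
    p_attack: Optional[float] = None
    q_defend: Optional[float] = None
    stay_prob: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.n_pairs < 1 or self.n_trials < 1:
            raise ValueError("n_pairs and n_trials must be >= 1")
        for prob in (self.p_attack, self.q_defend, self.stay_prob):
            if prob is not None and not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _bernoulli_actions(spec: GeneratorSpec, p: float, q: float):
    rng = np.random.default_rng(_seed_sequence(spec.seed))
    shape = (spec.n_pairs, spec.n_trials)
    return (rng.random(shape) < p).astype(np.int64), (
        rng.random(shape) < q
    ).astype(np.int64)


def _sticky_actions(spec: GeneratorSpec, p0: float, q0: float):
    """First trial ~ Bernoulli(p0/q0); afterwards repeat w.p. stay_prob."""
    rng = np.random.default_rng(_seed_sequence(spec.seed))
    shape = (spec.n_pairs, spec.n_trials)
    stay = rng.random(shape) < spec.stay_prob
    flip_a = (rng.random(shape) < 0.5).astype(np.int64)
    flip_d = (rng.random(shape) < 0.5).astype(np.int64)
    a = np.empty(shape, dtype=np.int64)
    d = np.empty(shape, dtype=np.int64)
    a[:, 0] = rng.random(spec.n_pairs) < p0
    d[:, 0] = rng.random(spec.n_pairs) < q0
    for t in range(1, spec.n_trials):
        a[:, t] = np.where(stay[:, t], a[:, t - 1], flip_a[:, t])
        d[:, t] = np.where(stay[:, t], d[:, t - 1], flip_d[:, t])
    return a, d


def generate(
    spec: GeneratorSpec, matrix: Optional[PayoffMatrix] = None
) -> pd.DataFrame:
    """Generate trial records for the requested agent kind.

    Payoffs are always recomputed from the condition's matrix, so the
    records satisfy the same bookkeeping invariants as simulated data.
    Reproducible from ``spec.seed``.
    """
    if matrix is None:
        matrix = make_condition(spec.condition)
    elif matrix.condition != spec.condition:
        raise ValueError(
            f"matrix condition {matrix.condition!r} does not match spec "
            f"condition {spec.condition!r}"
        )

    if spec.kind == "ibl":
        records, _ = run_condition(
            matrix,
            spec.adv_params,
            spec.def_params,
            n_pairs=spec.n_pairs,
            n_trials=spec.n_trials,
            seed=spec.seed,
        )
        return records

    if spec.kind in ("nash_bernoulli", "biased_bernoulli"):
        p, q = spec.p_attack, spec.q_defend
        if spec.kind == "nash_bernoulli":
            eq = solve_nash(matrix)
            p = eq.p if p is None else p
            q = eq.q if q is None else q
        if p is None or q is None:
            raise ValueError("biased_bernoulli requires p_attack and q_defend")
        a, d = _bernoulli_actions(spec, p, q)
    else:  # sticky
        p0 = 0.5 if spec.p_attack is None else spec.p_attack
        q0 = 0.5 if spec.q_defend is None else spec.q_defend
        a, d = _sticky_actions(spec, p0, q0)

    frames = []
    trials = np.arange(1, spec.n_trials + 1)
    for pair in range(spec.n_pairs):
        pa = np.array([matrix.adv_payoff[(x, y)] for x, y in zip(a[pair], d[pair])])
        pd_ = np.array([matrix.def_payoff[(x, y)] for x, y in zip(a[pair], d[pair])])
        frames.append(
            _records_frame(
                matrix, np.full(spec.n_trials, pair), trials, a[pair], d[pair], pa, pd_
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class RecoveryReport:
    """True vs. recovered parameters from a self-calibration run."""

    true_d: float
    true_sigma: float
    recovered: CalibrationResult
    fitness_true: float
    fitness_gap: float  # recovered minus true-parameter fitness


def recovery_report(
    true_params: Tuple[float, float],
    config: GAConfig,
    matrix: PayoffMatrix,
    n_pairs: int = 25,
    n_trials: int = 50,
) -> RecoveryReport:
    """Generate IBL data at known parameters, calibrate, and compare.

    The true parameters' own fitness (simulated with the calibration
    seeds against the same data) is the sampling-noise floor the
    recovered fitness is judged against.
    """
    d, sigma = true_params
    spec = GeneratorSpec(
        kind="ibl",
        condition=matrix.condition,
        n_pairs=n_pairs,
        n_trials=n_trials,
        seed=int(
            np.random.SeedSequence([config.seed, 0xDA]).generate_state(1)[0] % (2**31)
        ),
        adv_params=AgentParams(d=d, sigma=sigma),
        def_params=AgentParams(d=d, sigma=sigma),
    )
    data = generate(spec, matrix)
    result = calibrate_ga(data, matrix, config)
    target = ProportionSeries.from_records(data)
    sim_ss = np.random.SeedSequence([config.seed, 0xC1])
    fit_true = fitness(true_params, target, matrix, config, sim_seed=sim_ss)
    return RecoveryReport(
        true_d=d,
        true_sigma=sigma,
        recovered=result,
        fitness_true=fit_true,
        fitness_gap=result.fitness - fit_true,
    )
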