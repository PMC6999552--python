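# Methods

## Game and equilibrium baselines

The game is a simultaneous 2×2 interaction repeated over trials:
adversary actions {attack, not-attack}, defender actions {defend,
not-defend}, coded 1/0. Payoffs are integer points. Named conditions
share the adversary matrix (−10 for a caught attack, +5 for an
undetected one, 0 for not attacking) and vary the defender matrix; the
baseline defender payoffs are +5 for a caught attack, −5 for a miss, −5
for a false alarm, 0 otherwise. The penalty conditions raise the false
alarm (PDF) or the miss (PDM) penalty to −50; the generalization
conditions instead reward the defender's catch (RA) or the adversary's
undetected attack (RH) with +50. Two of the eight baseline entries
(defender's +5 for a catch, the zeros for inaction) are not stated
numerically anywhere we could source; they are fixed to the unique
values under which the indifference equations return the
conventionally reported equilibrium proportions (p = 1/3, 5/6, 1/12; q
= 1/3), and a regression test pins that consistency.

Equilibria are solved analytically in exact rational arithmetic: the
attack probability p makes the defender indifferent, the defend
probability q makes the adversary indifferent; when the interior
solution leaves [0,1] (or an indifference equation degenerates), pure
equilibria are enumerated by best response and a degeneracy flag is
set. A brute-force check — no profitable unilateral deviation, and
agreement with a grid minimizer of the maximal improvement — backs the
solver in the tests.

## The IBL agent

An instance is an (alternative, outcome) pair with the strictly
increasing list of trials at which that outcome followed that choice.
Activation at trial t is
`ln(Σ_{t_p} (t − t_p)^(−d)) + σ·ln((1−γ)/γ)` with γ drawn uniformly per
instance per trial (draws that land exactly on 0 or 1 are resampled).
Retrieval probabilities are a softmax of activations at temperature
τ = σ√2; the blended value of an alternative is the
retrieval-probability-weighted mean of its stored outcomes; the agent
chooses the argmax, breaking exact ties uniformly.

Design choices where the procedure was genuinely open:

- **Temperature rule.** σ×2 appears in some renderings of the
  retrieval equation; σ√2 is the standard form and is the default, with
  `times2` available as a switch (`AgentParams.tau_rule`).
- **First trial.** Memory is prepopulated with one synthetic instance
  per alternative at pseudo-trial 0, outcome equal to the agent's own
  role's largest absolute payoff (optimistic prepopulation, standard
  IBLT practice: it forces early exploration and keeps every lag ≥ 1).
  The value is configurable (`prepopulation_value`).
- **Noise caching.** One noise draw per instance per trial; the same
  activations feed both the retrieval probabilities and the blend
  within a trial.
- **Own outcomes only.** Only the chosen action's experienced outcome
  is stored; foregone and opponent payoffs are never learned, per the
  two-field instance structure.
- With σ = 0 the noise term is dropped and retrieval becomes argmax
  with uniform tie-splitting (the τ → 0 softmax limit); no division by
  zero occurs.

`IBLAgent.choose` inlines the activation/softmax/blend arithmetic in
pure Python for speed (small-array numpy overhead dominates at 2–6
instances); a test pins bit-level agreement with the functional
`blended_value` path under identically seeded generators.

## Simulation

A pair plays n_trials simultaneous rounds; each agent learns its own
payoff only. A condition run replicates independent pairs — the default
design is 25 pairs × 50 trials, the study size this package emulates —
and averages the 0/1 actions per trial into attack/defend proportion
series. Seeding uses `SeedSequence` spawning: every pair gets an
independent substream, so runs are bit-reproducible and adding pairs
never perturbs earlier ones. The generalization protocol replaces one
side with a memoryless Bernoulli "Nash bot" playing the condition's
equilibrium mix i.i.d. An initial endowment of 2500 points is tracked
for score reporting only; it never enters the choice rule.

## Synthetic behavioral data

The generator emulates the shape of the study's data (25 pairs × 50
trials per condition, binary action per role per trial, payoffs
recomputed from the condition matrix) with four ground-truth processes:
IBL pairs at known (d, σ); equilibrium-rate Bernoulli play;
arbitrary-rate Bernoulli play; and a sticky process that repeats its
previous action with probability 0.8 (a serial-dependence foil that is
not an IBL process). What it deliberately does not emulate: individual
differences (all pairs share parameters), payment incentives, fatigue
or session effects, and any coupling between role assignment and
behavior. Passing tests on these data therefore validate the machinery
(estimators, fitting, statistics) — they do not certify the model's fit
to any particular human population.

## Calibration

Fitness of a candidate (d, σ) — shared by both roles, mirroring random
role assignment — is the attack-channel plus defend-channel RMSD
between the candidate's simulated proportion series (25 replicated
pairs per evaluation by default) and the target series. The GA is
real-coded with tournament selection (size 2), BLX-0.5 crossover at
rate 0.8, per-gene Gaussian mutation at rate 0.01 (sd 5% of the [0, 30]
range, clipped), one-elite carryover, and stops after 50 generations
without improvement (hard cap 1000).

Stochastic fitness is handled with common random numbers: one fixed set
of simulation substreams is reused for every candidate throughout the
run, making fitness a deterministic, cacheable function of the genome
and the elite's best fitness exactly monotone. The alternative —
reseeding each generation — makes the stagnation rule ill-defined under
noise and was measurably slower without improving recovery.

**Identifiability.** The decay parameter is only weakly identified by
mean-series fitting: with σ free, widely different (d, σ) pairs produce
near-identical expected proportion series (differences ≲ 0.05 per
trial) while a 25-pair series carries ~0.1 sampling noise per trial.
Point estimates of d are therefore unstable across datasets, and
boundary pile-up of fitted d values should be expected. For regime
questions ("recency-driven vs. ACT-R-default behavior") use
`classify_regime`, which compares the calibration fitness of candidate
parameter sets averaged over independent seed blocks — a
likelihood-ratio-style comparison that discriminates the generating
regime reliably where thresholding d̂ does not. `recovery_report`
packages the full self-calibration experiment (generate at known
parameters, calibrate, compare fitness to the true parameters' own
replication-noise floor).

## Statistics

Participant-level mean proportions (one per pair per role) feed:
two-sided one-sample t tests against the Nash level with effect size
r = √(t²/(t²+df)); a between-subjects one-way ANOVA with
ω² = (SS_B − df_B·MS_W)/(SS_T + MS_W), reported as computed even if
slightly negative; and Student-Newman-Keuls stepwise post hoc
comparisons on the studentized-range distribution (widest span tested
first; a non-significant range blocks nested pairs; the equal-n
formulation, with a harmonic-mean fallback for unequal groups). α =
0.05 throughout; proportions are analyzed untransformed. Zero-variance
inputs return flagged degenerate results rather than exceptions.

## Numerical notes and problem sizes

- Equilibria: exact `Fraction` arithmetic; indifference residuals at
  the solution are < 1e-9 by construction.
- Activation sums accumulate left-to-right in double precision; the
  equation-oracle tests require 1e-12 agreement with independent
  recomputation.
- The test suite exercises directional penalty effects at 200 pairs per
  condition and parameter recovery at a reduced GA budget (population
  20, ≤ 100 generations, 25 replications per evaluation, 10 seeded
  runs) — sizes chosen to make the checks sharp while keeping the whole
  suite in the minutes range on one core.

## Known limitations

- Exact human proportion levels and published fit/generalization error
  tables depend on the original trial series and are not recomputable
  from synthetic data; only directional and structural properties are
  asserted.
- The blended-value agent is deterministic-argmax; probabilistic choice
  rules (e.g. choice softmax over blended values) are not implemented.
- Partial matching, spreading activation and similarity-graded recall
  are out of scope: the decision situation is constant, so instances
  reduce to (alternative, outcome).
- The GA assumes the equated-roles design; fitting separate adversary
  and defender parameters would need a 4-gene genome and is not
  provided.
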