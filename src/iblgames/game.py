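"""2x2 attacker-defender game: payoff conditions and mixed-strategy Nash solver.

The game is a simultaneous binary-choice game played repeatedly.  The
adversary chooses attack (1) or not-attack (0); the defender chooses defend
(1) or not-defend (0).  Payoffs are in game points.  Named conditions vary
the defender's penalty structure (false alarms vs. misses) or the
adversary's reward while holding the rest of the matrix fixed.

Conventions used throughout the package: the adversary indexes rows, the
defender columns; action code 1 means attack/defend, 0 means
not-attack/not-defend; joint actions are keyed ``(adv_action, def_action)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Tuple

JointAction = Tuple[int, int]

#: Joint actions in the canonical order (a,d), (a,nd), (na,d), (na,nd).
JOINT_ACTIONS: Tuple[JointAction, ...] = ((1, 1), (1, 0), (0, 1), (0, 0))

# Named payoff conditions, each as (adversary payoffs, defender payoffs)
# over the canonical joint-action order.  EQP is the equal-penalty
# baseline; PDF penalizes the defender 10x for false alarms (defend with
# no attack); PDM penalizes 10x for misses (no defend against an attack).
# EQ/RA/RH are the generalization conditions: EQ equals EQP, RA rewards
# the defender 10x for a caught attack, RH rewards the adversary 10x for
# an undetected attack.
_PRESETS: Dict[str, Tuple[Tuple[int, ...], Tuple[int, ...]]] = {
    "EQP": ((-10, 5, 0, 0), (5, -5, -5, 0)),
    "PDF": ((-10, 5, 0, 0), (5, -5, -50, 0)),
    "PDM": ((-10, 5, 0, 0), (5, -50, -5, 0)),
    "EQ": ((-10, 5, 0, 0), (5, -5, -5, 0)),
    "RA": ((-10, 5, 0, 0), (50, -5, -5, 0)),
    "RH": ((-10, 50, 0, 0), (5, -5, -5, 0)),
}

CONDITIONS = tuple(_PRESETS)


@dataclass(frozen=True)
class PayoffMatrix:
    """Payoffs for one condition of the 2x2 security game.

    Parameters
    ----------
    condition
        Condition label (one of the named presets, or ``"custom"``).
    adv_payoff
        Map from joint action ``(adv_action, def_action)`` to the
        adversary's payoff in points.
    def_payoff
        Same-shaped map for the defender.
    """

    condition: str
    adv_payoff: Dict[JointAction, float] = field(hash=False)
    def_payoff: Dict[JointAction, float] = field(hash=False)

    def __post_init__(self) -> None:
        for payoff in (self.adv_payoff, self.def_payoff):
            if set(payoff) != set(JOINT_ACTIONS):
                raise ValueError(
                    f"payoff map must cover exactly the joint actions {JOINT_ACTIONS}"
                )
            for v in payoff.values():
                if not (float("-inf") < float(v) < float("inf")):
                    raise ValueError("payoffs must be finite")

    def resolve(self, adv_action: int, def_action: int) -> Tuple[float, float]:
        """Payoff pair ``(adversary, defender)`` for a joint action."""
        return resolve_outcome(self, adv_action, def_action)

    def max_magnitude(self, role: str) -> float:
        """Largest absolute payoff the given role can experience."""
        payoff = self.adv_payoff if role == "adversary" else self.def_payoff
        return max(abs(v) for v in payoff.values())

    def to_dict(self) -> dict:
        keyed = lambda m: {f"{a}{d}": m[(a, d)] for a, d in JOINT_ACTIONS}
        return {
            "condition": self.condition,
            "adv_payoff": keyed(self.adv_payoff),
            "def_payoff": keyed(self.def_payoff),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PayoffMatrix":
        unkey = lambda m: {(int(k[0]), int(k[1])): v for k, v in m.items()}
        return cls(
            condition=data.get("condition", "custom"),
            adv_payoff=unkey(data["adv_payoff"]),
            def_payoff=unkey(data["def_payoff"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PayoffMatrix":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class NashSolution:
    """Mixed- or pure-strategy Nash equilibrium of a 2x2 game.

    ``p`` is the equilibrium probability of attack, ``q`` the probability
    of defend.  For an interior mixed equilibrium each player is exactly
    indifferent between their two actions against the opponent's mix.
    """

    p: float
    q: float
    adv_expected_payoff: float
    def_expected_payoff: float
    kind: str  # "mixed" or "pure"
    degenerate: bool = False


def make_condition(name: str) -> PayoffMatrix:
    """Build the payoff matrix for a named condition.

    Raises ``ValueError`` for an unknown name, listing the valid presets.
    """
    try:
        adv, dfn = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; valid presets: {', '.join(CONDITIONS)}"
        ) from None
    return PayoffMatrix(
        condition=name,
        adv_payoff=dict(zip(JOINT_ACTIONS, adv)),
        def_payoff=dict(zip(JOINT_ACTIONS, dfn)),
    )


def resolve_outcome(
    matrix: PayoffMatrix, adv_action: int, def_action: int
) -> Tuple[float, float]:
    """Look up the payoff pair ``(adv_points, def_points)`` for a joint action."""
    if adv_action not in (0, 1) or def_action not in (0, 1):
        raise ValueError("actions must be coded 0 or 1")
    key = (adv_action, def_action)
    return matrix.adv_payoff[key], matrix.def_payoff[key]


def _expected_payoffs(matrix: PayoffMatrix, p: Fraction, q: Fraction):
    """Expected payoff of each player when attack ~ Bern(p), defend ~ Bern(q)."""
    probs = {
        (1, 1): p * q,
        (1, 0): p * (1 - q),
        (0, 1): (1 - p) * q,
        (0, 0): (1 - p) * (1 - q),
    }
    ev_a = sum(probs[k] * Fraction(matrix.adv_payoff[k]) for k in JOINT_ACTIONS)
    ev_d = sum(probs[k] * Fraction(matrix.def_payoff[k]) for k in JOINT_ACTIONS)
    return ev_a, ev_d


def _pure_equilibria(matrix: PayoffMatrix):
    """All pure-strategy equilibria by best-response enumeration."""
    out = []
    for a in (0, 1):
        for d in (0, 1):
            adv_ok = matrix.adv_payoff[(a, d)] >= matrix.adv_payoff[(1 - a, d)]
            def_ok = matrix.def_payoff[(a, d)] >= matrix.def_payoff[(a, 1 - d)]
            if adv_ok and def_ok:
                out.append((a, d))
    return out


def solve_nash(matrix: PayoffMatrix) -> NashSolution:
    """Solve the 2x2 game analytically in exact rational arithmetic.

    An interior mixed equilibrium, when it exists, is found from the two
    indifference conditions: the attack probability ``p`` makes the
    defender indifferent between defending and not, and the defend
    probability ``q`` makes the adversary indifferent between attacking
    and not.  Otherwise pure equilibria are enumerated by best response.
    A game where an indifference equation degenerates (a player is
    indifferent for every opponent mix) is flagged ``degenerate`` and one
    equilibrium of the continuum is returned.
    """
    A = {k: Fraction(matrix.adv_payoff[k]) for k in JOINT_ACTIONS}
    D = {k: Fraction(matrix.def_payoff[k]) for k in JOINT_ACTIONS}

    # Defender indifference fixes p:  p*(D(a,d)-D(a,nd)) + (1-p)*(D(na,d)-D(na,nd)) = 0
    d_gain_attack = D[(1, 1)] - D[(1, 0)]
    d_gain_noattack = D[(0, 1)] - D[(0, 0)]
    # Adversary indifference fixes q:  q*(A(a,d)-A(na,d)) + (1-q)*(A(a,nd)-A(na,nd)) = 0
    a_gain_defend = A[(1, 1)] - A[(0, 1)]
    a_gain_nodefend = A[(1, 0)] - A[(0, 0)]

    denom_p = d_gain_noattack - d_gain_attack
    denom_q = a_gain_nodefend - a_gain_defend

    degenerate_p = denom_p == 0 and d_gain_noattack == 0
    degenerate_q = denom_q == 0 and a_gain_nodefend == 0

    if denom_p != 0 and denom_q != 0:
        p = d_gain_noattack / denom_p
        q = a_gain_nodefend / denom_q
        if 0 <= p <= 1 and 0 <= q <= 1:
            ev_a, ev_d = _expected_payoffs(matrix, p, q)
            return NashSolution(
                p=float(p),
                q=float(q),
                adv_expected_payoff=float(ev_a),
                def_expected_payoff=float(ev_d),
                kind="mixed",
            )

    pures = _pure_equilibria(matrix)
    if pures:
        a, d = pures[0]
        ev_a, ev_d = matrix.adv_payoff[(a, d)], matrix.def_payoff[(a, d)]
        return NashSolution(
            p=float(a),
            q=float(d),
            adv_expected_payoff=float(ev_a),
            def_expected_payoff=float(ev_d),
            kind="pure",
            degenerate=bool(degenerate_p or degenerate_q or len(pures) > 1),
        )

    raise ValueError(
        "no equilibrium found; a finite 2x2 game always has one -- check the matrix"
    )


def indifference_gaps(matrix: PayoffMatrix, p: float, q: float) -> Tuple[float, float]:
    """Per-player gap between the expected payoffs of their two actions.

    At an interior mixed equilibrium both gaps are zero.  Returned as
    ``(adversary_gap, defender_gap)``.
    """
    A, D = matrix.adv_payoff, matrix.def_payoff
    ev_attack = q * A[(1, 1)] + (1 - q) * A[(1, 0)]
    ev_noattack = q * A[(0, 1)] + (1 - q) * A[(0, 0)]
    ev_defend = p * D[(1, 1)] + (1 - p) * D[(0, 1)]
    ev_nodefend = p * D[(1, 0)] + (1 - p) * D[(0, 0)]
    return ev_attack - ev_noattack, ev_defend - ev_nodefend
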