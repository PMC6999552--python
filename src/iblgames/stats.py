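"""Statistical battery for attack/defend proportions.

Participant-level mean proportions feed three analyses: a one-sample t
test of each condition's proportions against the Nash prediction (effect
size r = sqrt(t^2 / (t^2 + df))), a between-subjects one-way ANOVA over
conditions (effect size omega squared), and Student-Newman-Keuls
stepwise post hoc comparisons on the studentized-range distribution.
Alpha is 0.05 and all tests are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p, effect size."""

    comparison: str
    statistic: float
    df: Union[float, Tuple[float, float]]
    p_value: float
    effect_size: Optional[float] = None
    significant: Optional[bool] = None
    degenerate: bool = False


def participant_proportions(records: pd.DataFrame, role: str) -> pd.DataFrame:
    """Per-participant mean action proportion for one role.

    Adversaries are scored on ``adv_action``, defenders on
    ``def_action``; one row per (condition, pair).  Raises if
    participants have unequal trial counts (ragged data).
    """
    if role not in ("adversary", "defender"):
        raise ValueError("role must be 'adversary' or 'defender'")
    if records.empty:
        raise ValueError("no records")
    col = "adv_action" if role == "adversary" else "def_action"
    grouped = records.groupby(["condition", "pair_id"], observed=True)[col]
    counts = grouped.count()
    if counts.nunique() != 1:
        raise ValueError("ragged trial counts across participants")
    out = grouped.mean().reset_index()
    out.columns = ["condition", "participant_id", "proportion"]
    out.insert(1, "role", role)
    return out


def one_sample_t(
    proportions: Sequence[float], nash_value: float, label: str = ""
) -> TestResult:
    """Two-sided one-sample t test of proportions against a Nash level."""
    x = np.asarray(proportions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    df = x.size - 1
    if np.ptp(x) == 0.0:
        # zero variance: report a flagged degenerate result, not an error
        if x[0] == nash_value:
            return TestResult(label, 0.0, df, 1.0, 0.0, False, degenerate=True)
        stat = math.copysign(math.inf, x[0] - nash_value)
        return TestResult(label, stat, df, 0.0, 1.0, True, degenerate=True)
    res = sps.ttest_1samp(x, nash_value)
    t = float(res.statistic)
    r = math.sqrt(t * t / (t * t + df))
    p = float(res.pvalue)
    return TestResult(label, t, df, p, r, p < ALPHA)


def one_way_anova(
    groups: Sequence[Sequence[float]], label: str = ""
) -> TestResult:
    """Between-subjects one-way ANOVA with omega-squared effect size.

    omega^2 = (SS_between - df_between * MS_within) / (SS_total + MS_within);
    it can come out slightly negative for tiny effects and is reported
    as computed.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between, df_within = k - 1, n_total - k
    if ss_within == 0.0:
        return TestResult(
            label,
            math.inf if ss_between > 0 else 0.0,
            (df_between, df_within),
            0.0 if ss_between > 0 else 1.0,
            1.0 if ss_between > 0 else 0.0,
            ss_between > 0,
            degenerate=True,
        )
    ms_within = ss_within / df_within
    f = (ss_between / df_between) / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    omega2 = (ss_between - df_between * ms_within) / (
        ss_between + ss_within + ms_within
    )
    return TestResult(label, float(f), (df_between, df_within), p, float(omega2), p < ALPHA)


def pairwise_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
) -> List[TestResult]:
    """Student-Newman-Keuls stepwise pairwise comparisons.

    Group means are ordered; each pair spanning ``r`` ordered means is
    tested on the studentized-range distribution with the span as the
    number of means.  Testing proceeds from the widest span inwards, and
    a non-significant range blocks every pair nested inside it (the
    stepwise rule).  Equal group sizes are assumed; unequal sizes fall
    back on the harmonic mean.  Returns one entry per group pair.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("one label per group required")
    anova = one_way_anova(arrays)
    df_within = anova.df[1]
    ns = np.array([a.size for a in arrays], dtype=float)
    n_h = len(ns) / np.sum(1.0 / ns)  # harmonic mean; equals n for equal groups
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_within = ss_within / df_within
    se = math.sqrt(ms_within / n_h) if ms_within > 0 else 0.0

    order = np.argsort([a.mean() for a in arrays])
    means = np.array([arrays[i].mean() for i in order])

    results: dict = {}
    blocked = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            pair = (order[i], order[j])
            diff = means[j] - means[i]
            if se == 0.0:
                q = math.inf if diff > 0 else 0.0
                p = 0.0 if diff > 0 else 1.0
                degenerate = True
            else:
                q = diff / se
                p = float(sps.studentized_range.sf(q, span, df_within))
                degenerate = False
            sig = (p < alpha) and not blocked[i, j]
            if not sig:
                # block every pair nested inside a non-significant range
                for ii in range(i, j + 1):
                    for jj in range(ii + 1, j + 1):
                        blocked[ii, jj] = True
            results[pair] = TestResult(
                f"{labels[pair[0]]} vs {labels[pair[1]]}",
                q,
                (span, df_within),
                p,
                None,
                sig,
                degenerate=degenerate,
            )
    # return in a stable (original-index) pair order
    ordered = []
    for a in range(k):
        for b in range(a + 1, k):
            ordered.append(results.get((a, b)) or results[(b, a)])
    return ordered


def condition_report(
    records: pd.DataFrame, nash_by_condition: dict
) -> pd.DataFrame:
    """Per-condition, per-role summary mirroring a standard results table.

    One row per (condition, role): mean proportion, the Nash prediction,
    and the one-sample t test of the participant proportions against it.
    """
    rows = []
    for role in ("adversary", "defender"):
        props = participant_proportions(records, role)
        for condition, sub in props.groupby("condition", observed=True):
            nash_p, nash_q = nash_by_condition[condition]
            nash = nash_p if role == "adversary" else nash_q
            res = one_sample_t(
                sub["proportion"].to_numpy(), nash, f"{condition}/{role}"
            )
            rows.append(
                {
                    "condition": condition,
                    "role": role,
                    "n": len(sub),
                    "mean_proportion": sub["proportion"].mean(),
                    "nash": nash,
                    "t": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "effect_r": res.effect_size,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)
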