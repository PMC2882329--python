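"""Variance-gated two-sample tests and Tukey-Kramer multiple comparisons.

Two groups are first compared with a two-sided F-test on their variances;
when the variances do not differ significantly (p >= 0.05) the means are
compared with the unpaired Student's t-test, otherwise with the unpaired
Welch's t-test (Satterthwaite degrees of freedom). Three or more groups go
through the Tukey-Kramer procedure (studentized range with unequal-n
standard errors). All tests are two-sided.

Summary-statistic variants accept (mean, SD, n) triplets so that published
group summaries can be re-tested without per-animal values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import StatsError

#: Significance level of the variance gate.
GATE_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one animal group: mean, sample SD and group size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise StatsError("standard deviation must be non-negative")
        if self.n < 2:
            raise StatsError("each group needs at least 2 animals")


@dataclass(frozen=True)
class GateDecision:
    """Outcome of the F-test variance gate."""

    choice: str  # "student" | "welch"
    f_statistic: float
    df: tuple[int, int]
    pvalue: float


@dataclass(frozen=True)
class StatResult:
    """One test outcome, with the gate decision trail when applicable."""

    test: str
    statistic: float
    df: float
    pvalue: float
    groups: tuple[str, str]
    gate: GateDecision | None = None

    @property
    def stars(self) -> str:
        if self.pvalue < 0.01:
            return "**"
        if self.pvalue < 0.05:
            return "*"
        return "N.S."


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean, sample SD (ddof=1) and n of raw per-animal values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise StatsError("each group needs at least 2 values")
    return GroupSummary(label=label, mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)


def f_variance_gate(a: GroupSummary, b: GroupSummary, alpha: float = GATE_ALPHA) -> GateDecision:
    """Two-sided F-test on the two variances; choose Welch iff p < alpha.

    The larger variance goes on top; two-sided p = min(1, 2 * upper tail).
    Two zero-variance groups are equal by definition (Student).
    """
    if a.sd == 0 and b.sd == 0:
        return GateDecision(choice="student", f_statistic=1.0, df=(a.n - 1, b.n - 1), pvalue=1.0)
    hi, lo = (a, b) if a.sd >= b.sd else (b, a)
    if lo.sd == 0:
        return GateDecision(
            choice="welch", f_statistic=np.inf, df=(hi.n - 1, lo.n - 1), pvalue=0.0
        )
    f = (hi.sd / lo.sd) ** 2
    dfn, dfd = hi.n - 1, lo.n - 1
    p = min(1.0, 2.0 * float(sps.f.sf(f, dfn, dfd)))
    return GateDecision(
        choice="welch" if p < alpha else "student", f_statistic=float(f), df=(dfn, dfd), pvalue=p
    )


def _t_from_summaries(a: GroupSummary, b: GroupSummary, kind: str) -> tuple[float, float, float]:
    if kind == "student":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    elif kind == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        if se == 0:
            df = a.n + b.n - 2
        else:
            df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        raise StatsError(f"unknown test kind {kind!r}; expected 'student' or 'welch'")
    diff = a.mean - b.mean
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), min(1.0, p)


def summary_ttest(
    a: GroupSummary, b: GroupSummary, kind: str | None = None
) -> StatResult:
    """Unpaired two-sided t-test from group summaries.

    ``kind`` forces Student or Welch; when None the F-test gate decides and
    its decision trail is attached to the result.
    """
    gate = None
    if kind is None:
        gate = f_variance_gate(a, b)
        kind = gate.choice
    t, df, p = _t_from_summaries(a, b, kind)
    return StatResult(
        test=kind, statistic=t, df=df, pvalue=p, groups=(a.label, b.label), gate=gate
    )


def sample_ttest(
    a_values: Sequence[float],
    b_values: Sequence[float],
    kind: str | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> StatResult:
    """Same tests on raw per-animal values; defined as :func:`summary_ttest`
    applied to the computed summaries, so the two routes agree exactly."""
    return summary_ttest(
        summarize(a_values, labels[0]), summarize(b_values, labels[1]), kind=kind
    )


def tukey_kramer(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[StatResult]:
    """Pairwise Tukey-Kramer comparisons for three or more groups.

    Uses the studentized range distribution with the pooled within-group
    variance and unequal-n standard errors ``sqrt(s2/2 * (1/ni + 1/nj))``.
    """
    if len(groups) < 3:
        raise StatsError(
            "Tukey-Kramer requires >= 3 groups; use the F-gated t-test for two"
        )
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise StatsError("each group needs at least 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    ns = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    k = len(arrs)
    df = int(ns.sum() - k)
    s2 = float(sum((a.size - 1) * a.var(ddof=1) for a in arrs) / df)
    results = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(s2 / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
        results.append(
            StatResult(
                test="tukey_kramer",
                statistic=float(q),
                df=float(df),
                pvalue=p,
                groups=(labels[i], labels[j]),
            )
        )
    return results


def compare_groups(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[StatResult]:
    """Dispatch on group count: gated t-test for two groups, Tukey-Kramer
    for three or more."""
    if len(groups) < 2:
        raise StatsError("need at least two groups to compare")
    if len(groups) == 2:
        if labels is None:
            labels = ("a", "b")
        return [sample_ttest(groups[0], groups[1], labels=(labels[0], labels[1]))]
    return tukey_kramer(groups, labels)
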