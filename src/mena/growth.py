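"""Growth-performance statistics: SGR, one-way ANOVA, Duncan's range test.

Specific growth rate is the standard aquaculture measure
SGR = (ln W_t - ln W_0) * 100 / t, in percent per day.  Group means are
compared by one-way ANOVA followed by Duncan's multiple range test, whose
result is reported as a compact letter display: groups sharing a letter are
not significantly different at the chosen alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ContractError


@dataclass
class GrowthRecord:
    """One replicate's weights: initial w0 (g), final wt (g), duration t (d)."""

    replicate: str
    group: str
    w0: float
    wt: float
    t: float

    def __post_init__(self):
        if self.w0 <= 0 or self.wt <= 0 or self.t <= 0:
            raise ContractError("weights and duration must be positive")


def sgr(w0, wt, t):
    """Specific growth rate (ln wt - ln w0) * 100 / t, percent per day."""
    if w0 <= 0 or wt <= 0:
        raise ContractError("weights must be positive")
    if t <= 0:
        raise ContractError("duration must be positive")
    return (math.log(wt) - math.log(w0)) * 100.0 / t


def one_way_anova(groups):
    """One-way ANOVA over a mapping of group label -> list of values.

    Returns (F, p).  Each group needs >= 2 values.
    """
    if len(groups) < 2:
        raise ContractError("need >= 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ContractError(f"group {label!r} has < 2 values")
    f, p = stats.f_oneway(*[np.asarray(v, dtype=float)
                            for v in groups.values()])
    return float(f), float(p)


def _anova_mse(groups):
    """Within-group mean square and its degrees of freedom."""
    n_total = sum(len(v) for v in groups.values())
    k = len(groups)
    ss_within = sum(
        ((np.asarray(v, dtype=float) - np.mean(v)) ** 2).sum()
        for v in groups.values())
    df = n_total - k
    return ss_within / df, df


def duncan_mrt(groups, alpha=0.05):
    """Duncan's multiple range test with a compact letter display.

    Group means are sorted and spans compared against Duncan's least
    significant range LSR_p = q_p * sqrt(MSE / n_h), where q_p is the
    studentized-range quantile at Duncan's protection level
    alpha_p = 1 - (1 - alpha)^(p-1) for a span of p means, and n_h is the
    harmonic mean group size.  The step-down rule applies: a span whose
    range is not significant is declared homogeneous and not subdivided.

    Returns a dict group label -> letter string (e.g. ``"a"``, ``"ab"``).
    """
    if len(groups) < 2:
        raise ContractError("need >= 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ContractError(f"group {label!r} has < 2 values")
    mse, df = _anova_mse(groups)
    ns = [len(v) for v in groups.values()]
    n_h = len(ns) / sum(1.0 / n for n in ns)
    labels = sorted(groups, key=lambda g: -np.mean(groups[g]))
    means = [float(np.mean(groups[g])) for g in labels]
    k = len(labels)

    if mse == 0:
        # no within-group noise: any difference in means separates groups
        seen = {}
        for i, m in enumerate(means):
            seen.setdefault(round(m, 12), []).append(i)
        homogeneous = [(idx[0], idx[-1]) for idx in seen.values()]
        return _letters(labels, homogeneous, k)

    def lsr(p):
        q = stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df)
        return q * math.sqrt(mse / n_h)

    homogeneous = []

    def test(i, j):
        if i >= j:
            return
        p = j - i + 1
        if means[i] - means[j] < lsr(p):
            homogeneous.append((i, j))
            return
        test(i, j - 1)
        test(i + 1, j)

    test(0, k - 1)
    return _letters(labels, homogeneous, k)


def _letters(labels, homogeneous, k):
    """Compact letter display from homogeneous (i, j) spans (sorted order)."""
    # keep maximal spans only; every group must be covered
    uniq = sorted(set(homogeneous))
    spans = [s for s in uniq
             if not any(a <= s[0] and s[1] <= b and (a, b) != s
                        for a, b in uniq)]
    covered = set()
    for i, j in spans:
        covered.update(range(i, j + 1))
    for i in range(k):
        if i not in covered:
            spans.append((i, i))
    spans.sort()
    letters = {lab: "" for lab in labels}
    for idx, (i, j) in enumerate(spans):
        letter = chr(ord("a") + idx)
        for g in range(i, j + 1):
            letters[labels[g]] += letter
    return letters


@dataclass
class GroupComparison:
    """Per-group summary with ANOVA F/p and Duncan letters."""

    labels: list
    means: dict
    sds: dict
    f_statistic: float
    p_value: float
    letters: dict
    alpha: float


def compare_groups(groups, alpha=0.05):
    """ANOVA + Duncan's MRT over group label -> values."""
    f, p = one_way_anova(groups)
    letters = duncan_mrt(groups, alpha=alpha)
    return GroupComparison(
        labels=list(groups),
        means={g: float(np.mean(v)) for g, v in groups.items()},
        sds={g: float(np.std(v, ddof=1)) for g, v in groups.items()},
        f_statistic=f,
        p_value=p,
        letters=letters,
        alpha=alpha,
    )


def sgr_table(records):
    """Group replicate-level SGRs from GrowthRecord rows."""
    groups = {}
    for r in records:
        groups.setdefault(r.group, []).append(sgr(r.w0, r.wt, r.t))
    return groups
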