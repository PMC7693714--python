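"""Statistical layer: Student's t-test, one-way ANOVA and Duncan's multiple
range test with compact-letter groupings at alpha = 0.05.

Duncan's test compares the sorted group means stepwise: a span of p adjacent
ordered means is declared heterogeneous when its range exceeds the critical
range

    R_p = q*(alpha_p, p, df) * sqrt(MS_within / n_h),

where q* is the studentized-range quantile at the protection level
alpha_p = 1 - (1 - alpha)^(p-1) and n_h the harmonic mean of the group sizes.
Letters mark the maximal non-significant spans (contiguous in the ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupedSample:
    """Named groups of observations for ANOVA / Duncan."""

    groups: dict[str, np.ndarray]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if any(len(v) < 2 for v in self.groups.values()):
            raise ValueError("each group needs n >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def t_test(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-sided Student's t-test (classical, equal-variance by default).

    Degenerate samples with zero pooled variance and equal means return
    (0.0, 1.0) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    if not paired and a.std() == 0 and b.std() == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    if paired:
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    return stat, p


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float


def one_way_anova(sample: GroupedSample) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA decomposition.

    The full sum-of-squares decomposition is returned because Duncan's test
    consumes MS_within and df_within.  All-constant data yield F = 0, p = 1.
    """
    values = list(sample.groups.values())
    all_vals = np.concatenate(values)
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_between = len(values) - 1
    df_within = len(all_vals) - len(values)
    if df_within < 1:
        raise ValueError("no within-group degrees of freedom")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if np.isclose(ss_between, 0):
            return AnovaResult(0.0, 1.0, df_between, df_within, ms_between, 0.0)
        return AnovaResult(np.inf, 0.0, df_between, df_within, ms_between, 0.0)
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), p, df_between, df_within, float(ms_between), float(ms_within))


def duncan_protection_level(alpha: float, p_span: int) -> float:
    """Duncan's per-span significance level alpha_p = 1 - (1-alpha)^(p-1)."""
    return 1.0 - (1.0 - alpha) ** (p_span - 1)


def duncan_critical_range(alpha: float, p_span: int, df_within: int, ms_within: float,
                          n_harmonic: float) -> float:
    """Critical range R_p for a span of ``p_span`` ordered means."""
    alpha_p = duncan_protection_level(alpha, p_span)
    q = sps.studentized_range.ppf(1.0 - alpha_p, p_span, df_within)
    return float(q * np.sqrt(ms_within / n_harmonic))


@dataclass
class DuncanResult:
    """Ordered means with compact letters and span-wise critical ranges."""

    means: pd.DataFrame  # columns: group, n, mean, letters (sorted descending)
    critical_ranges: dict[int, float]  # span -> R_p
    different: dict[tuple[str, str], bool]  # pairwise decisions
    alpha: float = 0.05


def duncan_mrt(sample: GroupedSample, anova: AnovaResult | None = None) -> DuncanResult:
    """Duncan's multiple range test with compact-letter display.

    Two means differ iff the range of the ordered span they delimit exceeds
    R_p for that span size *and* they are not contained in any wider
    non-significant span (the standard stepwise protection).  Letters are the
    maximal non-significant spans, so they are contiguous in the ordering.
    """
    if anova is None:
        anova = one_way_anova(sample)
    if anova.df_within < 1:
        raise ValueError("Duncan requires df_within >= 1")
    names = list(sample.groups)
    means = np.array([sample.groups[g].mean() for g in names])
    ns = np.array([len(sample.groups[g]) for g in names])
    order = np.argsort(-means)
    names_o = [names[i] for i in order]
    means_o = means[order]
    k = len(names)
    n_h = k / np.sum(1.0 / ns)
    ranges = {
        span: duncan_critical_range(sample.alpha, span, anova.df_within, anova.ms_within, n_h)
        for span in range(2, k + 1)
    }
    # homogeneous[i][j]: ordered span i..j (inclusive) within its critical range
    homog = np.zeros((k, k), dtype=bool)
    for i in range(k):
        homog[i, i] = True
        for j in range(i + 1, k):
            span = j - i + 1
            homog[i, j] = (means_o[i] - means_o[j]) <= ranges[span]
    # protection: any span inside a homogeneous span is homogeneous
    covered = homog.copy()
    for i in range(k):
        for j in range(i + 1, k):
            if homog[i, j]:
                covered[i:j + 1, i:j + 1] |= np.triu(np.ones((j - i + 1, j - i + 1), dtype=bool))
    # letters: maximal homogeneous spans
    spans = []
    for i in range(k):
        j = i
        while j + 1 < k and covered[i, j + 1]:
            j += 1
        spans.append((i, j))
    maximal = [s for s in spans if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in spans)]
    maximal.sort()
    letters = ["" for _ in range(k)]
    for idx, (i, j) in enumerate(maximal):
        letter = chr(ord("a") + idx)
        for m in range(i, j + 1):
            letters[m] += letter
    different: dict[tuple[str, str], bool] = {}
    for i in range(k):
        for j in range(i + 1, k):
            pair = tuple(sorted((names_o[i], names_o[j])))
            different[pair] = not covered[i, j]
    df = pd.DataFrame(
        {"group": names_o, "n": ns[order], "mean": means_o, "letters": letters}
    )
    return DuncanResult(means=df, critical_ranges=ranges, different=different, alpha=sample.alpha)


def mark_vs_reference(
    sample: GroupedSample, reference: str, paired: bool = False
) -> pd.DataFrame:
    """Flag groups significantly different from a reference group (t-test).

    Mirrors the figure convention of marking each later timepoint that differs
    from the reference day at p < alpha with an asterisk; no multiple-testing
    correction is applied across timepoints.
    """
    if reference not in sample.groups:
        raise KeyError(f"reference group {reference!r} not present")
    ref = sample.groups[reference]
    rows = []
    for name, vals in sample.groups.items():
        if name == reference:
            continue
        stat, p = t_test(ref, vals, paired=paired)
        rows.append(
            {"group": name, "t": stat, "p": p, "significant": p < sample.alpha}
        )
    return pd.DataFrame(rows)


def grouped_from_long(df: pd.DataFrame, group_col: str = "group", value_col: str = "value",
                      alpha: float = 0.05) -> GroupedSample:
    """Build a GroupedSample from a long-format (group, value) table."""
    return GroupedSample(
        {str(g): sub[value_col].to_numpy() for g, sub in df.groupby(group_col)}, alpha=alpha
    )
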