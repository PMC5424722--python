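"""Group summaries and Fisher LSD multiple comparisons.

After a one-way ANOVA over the three viability groups, Fisher's least
significant difference (LSD) procedure compares each pair of group
means using the pooled error mean square:

    SE(i, j) = sqrt(MS_e * (1/n_i + 1/n_j)),
    t = (mean_i - mean_j) / SE,   compared to t_{alpha/2}(df_e),

with df_e = N - k.  For equal group sizes the SE reduces to the
textbook sqrt(2 * MS_e / n).  No family-wise correction is applied
beyond the LSD procedure itself — each pairwise test runs at the
nominal alpha, which is the convention this analysis follows
deliberately (and documents, rather than hides).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import harmonic_mean

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUP_ORDER",
    "GroupSummary",
    "AnovaResult",
    "LSDComparison",
    "summarize_groups",
    "anova_mse",
    "lsd_pairwise",
    "lsd_table",
]

GROUP_ORDER = ("viable", "aged", "non_viable")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and SD for one parameter."""

    parameter: str
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA error term for one parameter."""

    parameter: str
    ms_e: float
    df_e: int
    group_means: dict[str, float]
    group_ns: dict[str, int]


@dataclass(frozen=True)
class LSDComparison:
    """One ordered pairwise comparison (i minus j)."""

    parameter: str
    group_i: str
    group_j: str
    mean_difference: float
    std_error: float
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    significant_at_005: bool


def _group_values(values, labels) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    groups = {}
    for g in GROUP_ORDER:
        sel = values[labels == g]
        if sel.size:
            groups[g] = sel
    extra = set(np.unique(labels)) - set(GROUP_ORDER)
    if extra:
        raise ValueError(f"unknown group labels: {sorted(extra)}")
    return groups


def summarize_groups(features: pd.DataFrame, labels) -> list[GroupSummary]:
    """Sample mean and SD (n-1 denominator) per parameter per group."""
    labels = np.asarray(labels)
    out = []
    for col in features.columns:
        if features[col].dtype == bool:
            continue
        groups = _group_values(features[col].to_numpy(float), labels)
        for g, vals in groups.items():
            if vals.size < 2:
                raise ValueError(
                    f"group {g!r} has {vals.size} member(s); need >= 2 for an SD"
                )
        out.append(GroupSummary(
            parameter=col,
            n={g: int(v.size) for g, v in groups.items()},
            mean={g: float(np.nanmean(v)) for g, v in groups.items()},
            sd={g: float(np.nanstd(v, ddof=1)) for g, v in groups.items()},
        ))
    return out


def anova_mse(values, labels, parameter: str = "") -> AnovaResult:
    """Pooled within-group mean square: MS_e = SS_within / (N - k)."""
    groups = _group_values(values, labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 members")
    n_total = sum(v.size for v in groups.values())
    k = len(groups)
    ss_e = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    return AnovaResult(
        parameter=parameter,
        ms_e=ss_e / (n_total - k),
        df_e=n_total - k,
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_ns={g: int(v.size) for g, v in groups.items()},
    )


def lsd_pairwise(anova: AnovaResult, alpha: float = 0.05,
                 equal_n_mode: bool = False) -> list[LSDComparison]:
    """All ordered pairwise LSD comparisons for one parameter.

    ``equal_n_mode=True`` replaces the pair-specific sample sizes with
    a single common n (the harmonic mean of the group sizes), i.e. the
    textbook equal-n standard error sqrt(2 * MS_e / n); with genuinely
    equal group sizes the two modes agree exactly.
    """
    groups = [g for g in GROUP_ORDER if g in anova.group_means]
    crit = float(sps.t.ppf(1.0 - alpha / 2.0, anova.df_e))
    n_common = harmonic_mean([anova.group_ns[g] for g in groups])
    out = []
    for gi in groups:
        for gj in groups:
            if gi == gj:
                continue
            diff = anova.group_means[gi] - anova.group_means[gj]
            if equal_n_mode:
                se = float(np.sqrt(2.0 * anova.ms_e / n_common))
            else:
                se = float(np.sqrt(anova.ms_e * (1.0 / anova.group_ns[gi]
                                                 + 1.0 / anova.group_ns[gj])))
            if se == 0.0:
                t_stat = 0.0 if diff == 0.0 else float(np.inf) * np.sign(diff)
                p = 1.0 if diff == 0.0 else 0.0
            else:
                t_stat = diff / se
                p = float(2.0 * sps.t.sf(abs(t_stat), anova.df_e))
            out.append(LSDComparison(
                parameter=anova.parameter, group_i=gi, group_j=gj,
                mean_difference=diff, std_error=se, t_statistic=t_stat,
                p_value=p, ci_low=diff - crit * se, ci_high=diff + crit * se,
                significant_at_005=p < alpha,
            ))
    return out


def lsd_table(features: pd.DataFrame, labels, alpha: float = 0.05,
              equal_n_mode: bool = False) -> pd.DataFrame:
    """LSD comparisons for every numeric feature column, as one table."""
    labels = np.asarray(labels)
    rows = []
    for col in features.columns:
        if features[col].dtype == bool:
            continue
        anova = anova_mse(features[col].to_numpy(float), labels, parameter=col)
        for comp in lsd_pairwise(anova, alpha, equal_n_mode):
            rows.append({
                "parameter": comp.parameter, "group_i": comp.group_i,
                "group_j": comp.group_j,
                "mean_difference": comp.mean_difference,
                "std_error": comp.std_error, "t": comp.t_statistic,
                "p_value": comp.p_value, "ci_low": comp.ci_low,
                "ci_high": comp.ci_high,
                "significant": comp.significant_at_005,
            })
    return pd.DataFrame(rows)
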