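"""Cross-cluster comparison: one-way ANOVA, Tukey–Kramer pairs, summaries.

Given hard cluster assignments, each variable (clustering variable or health
outcome) is tested for an overall mean difference across clusters with a
classical one-way ANOVA, and pairs of clusters are compared with Tukey's
honestly-significant-difference test in its Tukey–Kramer form, which handles
unequal cluster sizes via the standard error
sqrt(MS_within · (1/n_a + 1/n_b) / 2). Adjusted p-values and simultaneous
confidence intervals come from the studentized-range distribution with
(#groups, N − #groups) parameters.

Cluster description tables code each cluster's mean on every variable as
low / medium / high by ranking the cluster means and cutting the rank range
at terciles, and label clusters with the modal NCHS urban-rural class of
their member counties.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data import NCHS_LABELS


@dataclass
class AnovaResult:
    variable: str
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class TukeyPair:
    group_a: int
    group_b: int
    mean_diff: float  # mean(b) − mean(a)
    se: float
    q_stat: float
    ci_low: float
    ci_high: float
    p_adj: float
    significant: bool


@dataclass
class ClusterSummary:
    cluster: int
    size: int
    levels: dict  # variable -> "low" | "medium" | "high"
    nchs_label: str


def _group_arrays(values, labels):
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if values.size != labels.size:
        raise ValueError("values and labels must have equal length")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    arrs = [values[labels == g] for g in groups]
    small = [g for g, a in zip(groups, arrs) if a.size < 2]
    if small:
        raise ValueError(f"group(s) with fewer than 2 observations: {small}")
    return groups, arrs


def anova_oneway(values, labels, variable: str = "") -> AnovaResult:
    """Classical one-way ANOVA of `values` grouped by `labels`.

    F = MS_between / MS_within with (G−1, N−G) degrees of freedom. Degenerate
    inputs are guarded: zero between-group variation gives F = 0; zero
    within-group variation with nonzero between gives p = 0 rather than NaN.
    """
    groups, arrs = _group_arrays(values, labels)
    n = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    dfb, dfw = groups.size - 1, n - groups.size
    if ss_between <= 0:
        f = 0.0
    elif ss_within <= 0:
        return AnovaResult(variable, np.inf, dfb, dfw, 0.0)
    else:
        f = (ss_between / dfb) / (ss_within / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(variable, float(f), dfb, dfw, p)


@lru_cache(maxsize=256)
def _studentized_range_crit(alpha: float, groups: int, dfw: int) -> float:
    """1−alpha quantile of the studentized range (cached: ppf is costly)."""
    return float(stats.studentized_range.ppf(1 - alpha, groups, dfw))


def tukey_hsd(values, labels, alpha: float = 0.001) -> list[TukeyPair]:
    """All pairwise Tukey–Kramer comparisons of group means.

    For each unordered pair (a, b) with a < b the statistic is
    q = |ȳ_b − ȳ_a| / SE with SE = sqrt(MS_within (1/n_a + 1/n_b) / 2);
    the adjusted p-value is the studentized-range tail probability with
    (#groups, N − #groups) parameters, and the 1 − alpha simultaneous CI is
    mean_diff ± q_crit · SE.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    groups, arrs = _group_arrays(values, labels)
    g = groups.size
    n = sum(a.size for a in arrs)
    dfw = n - g
    ms_within = sum(((a - a.mean()) ** 2).sum() for a in arrs) / dfw
    if ms_within <= 0:
        raise ValueError("zero within-group variance; Tukey SE undefined")
    q_crit = _studentized_range_crit(alpha, g, dfw)
    out = []
    means = {gr: a.mean() for gr, a in zip(groups, arrs)}
    sizes = {gr: a.size for gr, a in zip(groups, arrs)}
    for a, b in combinations(groups, 2):
        se = np.sqrt(ms_within * (1.0 / sizes[a] + 1.0 / sizes[b]) / 2.0)
        diff = means[b] - means[a]
        q = abs(diff) / se
        p_adj = float(np.clip(stats.studentized_range.sf(q, g, dfw), 0.0, 1.0))
        out.append(TukeyPair(
            group_a=int(a), group_b=int(b), mean_diff=float(diff),
            se=float(se), q_stat=float(q),
            ci_low=float(diff - q_crit * se), ci_high=float(diff + q_crit * se),
            p_adj=p_adj, significant=bool(p_adj < alpha)))
    return out


def significant_pairs(pairs: list[TukeyPair], alpha: float) -> list[tuple]:
    """Cluster pairs with adjusted p below alpha, sorted lexicographically."""
    keep = [(min(p.group_a, p.group_b), max(p.group_a, p.group_b))
            for p in pairs if p.p_adj < alpha]
    return sorted(keep)


def format_pairs(pairs: list[tuple]) -> str:
    """Render pairs in the "(a, b)(c, d)" table style."""
    return "".join(f"({a}, {b})" for a, b in pairs)


def _tercile_levels(cluster_means: dict) -> dict:
    """Code cluster means low/medium/high by terciles of the rank range."""
    items = sorted(cluster_means.items(), key=lambda kv: kv[1])
    g = len(items)
    if g == 1:
        return {items[0][0]: "medium"}
    levels = {}
    for rank, (cl, _) in enumerate(items):
        frac = rank / (g - 1)
        levels[cl] = "low" if frac < 1 / 3 else ("medium" if frac < 2 / 3 else "high")
    return levels


def summarize_clusters(labels, table: pd.DataFrame, variables: list[str],
                       outcomes: list[str] = ()) -> list[ClusterSummary]:
    """Per-cluster sizes, low/medium/high variable coding, and NCHS label.

    `labels` must align row-for-row with `table`. The low/medium/high coding
    ranks each variable's cluster means and cuts the rank range at terciles;
    a lone cluster codes as "medium" (no contrast).
    """
    labels = np.asarray(labels).ravel()
    if labels.size != len(table):
        raise ValueError("labels and table are misaligned")
    clusters = sorted(np.unique(labels).tolist())
    cols = list(variables) + [c for c in outcomes if c not in variables]
    level_maps = {}
    for col in cols:
        means = {cl: float(table.loc[labels == cl, col].mean()) for cl in clusters}
        level_maps[col] = _tercile_levels(means)
    out = []
    for cl in clusters:
        mask = labels == cl
        if "nchs_class" in table.columns:
            mode = Counter(table.loc[mask, "nchs_class"].astype(int)).most_common(1)
            nchs = NCHS_LABELS.get(mode[0][0], str(mode[0][0]))
        else:
            nchs = "n/a"
        out.append(ClusterSummary(
            cluster=int(cl), size=int(mask.sum()),
            levels={c: level_maps[c][cl] for c in cols}, nchs_label=nchs))
    return out


@dataclass
class ComparisonReport:
    """Per-variable ANOVA + Tukey tables across clusters, at a common alpha."""

    alpha: float
    anova: dict  # variable -> AnovaResult
    tukey: dict  # variable -> list[TukeyPair]

    def significant(self) -> dict:
        return {v: significant_pairs(pairs, self.alpha)
                for v, pairs in self.tukey.items()}

    def anova_frame(self) -> pd.DataFrame:
        rows = [vars(a) for a in self.anova.values()]
        return pd.DataFrame(rows)

    def tukey_frame(self) -> pd.DataFrame:
        rows = []
        for v, pairs in self.tukey.items():
            for p in pairs:
                rows.append({"variable": v, **vars(p)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Cluster comparison (alpha = {self.alpha})", "=" * 60,
                 "One-way ANOVA:"]
        for v, a in self.anova.items():
            lines.append(
                f"  {v:>20s}  F({a.df_between}, {a.df_within}) = "
                f"{a.f_stat:8.2f}   p = {a.p_value:.3g}")
        lines += ["", f"Significant Tukey pairs (p < {self.alpha}):"]
        for v, pairs in self.significant().items():
            lines.append(f"  {v:>20s}  {format_pairs(pairs) or '(none)'}")
        return "\n".join(lines)


def compare_clusters(table: pd.DataFrame, labels, variables: list[str],
                     alpha: float = 0.001) -> ComparisonReport:
    """ANOVA + Tukey for each named column of `table` across `labels`.

    Singleton clusters carry no within-group information and are dropped
    from the comparison (with a warning) rather than failing the run.
    """
    import warnings

    labels = np.asarray(labels).ravel()
    sizes = {g: int((labels == g).sum()) for g in np.unique(labels)}
    singletons = [g for g, s in sizes.items() if s < 2]
    keep = np.isin(labels, [g for g, s in sizes.items() if s >= 2])
    if singletons:
        warnings.warn(f"dropping singleton cluster(s) {singletons} from the "
                      "comparison", stacklevel=2)
    anova = {}
    tukey = {}
    for v in variables:
        vals = table[v].to_numpy(dtype=float)[keep]
        anova[v] = anova_oneway(vals, labels[keep], variable=v)
        tukey[v] = tukey_hsd(vals, labels[keep], alpha=alpha)
    return ComparisonReport(alpha=alpha, anova=anova, tukey=tukey)
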