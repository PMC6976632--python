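"""Folded / Partially Folded / Unfolded classes and group statistics.

Proteins are classified by predicted disorder fraction: Folded (F) below 10%,
Partially Folded (P) from 10% to 30%, Unfolded (U) above 30%. The printed
ranges "<10%", "10-30%", ">30%" leave the boundaries ambiguous; both 10% and
30% are assigned to P here so every stated range is honored literally:
F = [0, 0.10), P = [0.10, 0.30], U = (0.30, 1].

Per-protein biotin counts are compared across classes on a log2 scale with a
pseudo-count (default 0.5, which keeps zero counts strictly below the zero
line) via pairwise t-tests (Welch by default), one-way ANOVA, and Tukey's HSD
with Tukey-Kramer handling of unbalanced classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLASS_LABELS = ("F", "P", "U")
PAIR_ORDER = (("F", "P"), ("U", "P"), ("U", "F"))


def classify_protein(fraction: float) -> str:
    """Map a disorder fraction to its structural class (F, P or U)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"disorder fraction {fraction} outside [0, 1]")
    if fraction < 0.10:
        return "F"
    if fraction <= 0.30:
        return "P"
    return "U"


def classify_proteins(fractions: Mapping[str, float]) -> pd.DataFrame:
    rows = [(acc, f, classify_protein(f)) for acc, f in fractions.items()]
    return pd.DataFrame(rows, columns=["accession", "fraction", "class"])


def log2_counts(counts, pseudo: float = 0.5) -> np.ndarray:
    """log2(count + pseudo); with the default pseudo, zero counts map to -1."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    return np.log2(counts + pseudo)


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    mean_diff: float  # mean(a) - mean(b)
    statistic: float
    df: float
    p_value: float
    welch: bool


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    ci_low: float
    ci_high: float
    p_adj: float


@dataclass
class ClassComparison:
    pairwise: list[PairwiseTest] = field(default_factory=list)
    anova: AnovaResult | None = None
    tukey: list[TukeyPair] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.pairwise:
            kind = "welch_t" if t.welch else "pooled_t"
            rows.append(
                (kind, f"{t.group_a}-{t.group_b}", t.mean_diff, t.statistic, t.df,
                 t.p_value, np.nan, np.nan)
            )
        if self.anova is not None:
            rows.append(
                ("anova", "all", np.nan, self.anova.statistic,
                 self.anova.df_within, self.anova.p_value, np.nan, np.nan)
            )
        for t in self.tukey:
            rows.append(
                ("tukey_hsd", f"{t.group_a}-{t.group_b}", t.mean_diff, np.nan,
                 np.nan, t.p_adj, t.ci_low, t.ci_high)
            )
        return pd.DataFrame(
            rows,
            columns=["test", "groups", "mean_diff", "statistic", "df", "p_value",
                     "ci_low", "ci_high"],
        )


def anova_oneway(groups: Sequence[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA; degenerate all-equal data yields F = 0."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else float("inf")
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(statistic=float(f), df_between=df_b, df_within=df_w, p_value=p)


def tukey_hsd(
    values_by_group: Mapping[str, np.ndarray], alpha: float = 0.05
) -> list[TukeyPair]:
    """Tukey's Honestly Significant Differences over all group pairs.

    Uses the studentized-range distribution with the Tukey-Kramer standard
    error ``sqrt(MSE/2 * (1/n_i + 1/n_j))`` for unbalanced groups. Adjusted
    p-values control the family-wise error rate; confidence intervals are
    symmetric about each mean difference at level 1 - alpha.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations for Tukey HSD")
    k = len(names)
    n = sum(len(g) for g in groups)
    df = n - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    out = []
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df)) if mse > 0 else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = gi.mean() - gj.mean()
            se = np.sqrt(mse / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
            if se == 0.0:
                p_adj = 1.0 if diff == 0.0 else 0.0
                half = 0.0
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df))
                half = q_crit * se
            out.append(
                TukeyPair(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=float(diff),
                    ci_low=float(diff - half),
                    ci_high=float(diff + half),
                    p_adj=min(1.0, p_adj),
                )
            )
    return out


def compare_classes(
    values_by_class: Mapping[str, Sequence[float]],
    welch: bool = True,
    alpha: float = 0.05,
) -> ClassComparison:
    """Pairwise t-tests (F-P, U-P, U-F), one-way ANOVA, and Tukey HSD.

    Classes with fewer than 2 observations are skipped with a warning for the
    pairwise tests and excluded from ANOVA/Tukey; if fewer than two usable
    classes remain the comparison is an error.
    """
    data = {
        g: np.asarray(v, dtype=float)
        for g, v in values_by_class.items()
        if len(v) > 0
    }
    usable = {g: v for g, v in data.items() if len(v) >= 2}
    skipped = sorted(set(data) - set(usable))
    if skipped:
        warnings.warn(
            f"classes with < 2 observations skipped: {skipped}", stacklevel=2
        )
    if len(usable) < 2:
        raise ValueError("need >= 2 classes with >= 2 observations")

    result = ClassComparison()
    pairs = [p for p in PAIR_ORDER if p[0] in usable and p[1] in usable]
    # any extra class labels beyond F/P/U: compare in sorted order
    extra = sorted(g for g in usable if g not in CLASS_LABELS)
    for i, a in enumerate(extra):
        for b in list(usable)[: i + 1]:
            if (a, b) not in pairs and (b, a) not in pairs and a != b:
                pairs.append((a, b))
    for a, b in pairs:
        va, vb = usable[a], usable[b]
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va.mean() == vb.mean():
            t_stat, p, df = 0.0, 1.0, float(len(va) + len(vb) - 2)
        else:
            res = stats.ttest_ind(va, vb, equal_var=not welch)
            t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        result.pairwise.append(
            PairwiseTest(
                group_a=a,
                group_b=b,
                mean_diff=float(va.mean() - vb.mean()),
                statistic=t_stat,
                df=df,
                p_value=p,
                welch=welch,
            )
        )
    result.anova = anova_oneway(list(usable.values()))
    result.tukey = tukey_hsd(usable, alpha=alpha)
    return result


def class_values(
    summaries: pd.DataFrame, pseudo: float = 0.5
) -> dict[str, np.ndarray]:
    """Split log2-transformed biotin counts by structural class.

    Expects the per-protein summary table (columns ``biotin_count`` and
    ``disorder_fraction``); returns the bean-plot-ready mapping class ->
    log2(count + pseudo) values.
    """
    classes = summaries["disorder_fraction"].map(classify_protein)
    out: dict[str, np.ndarray] = {}
    for label in CLASS_LABELS:
        vals = summaries.loc[classes == label, "biotin_count"].to_numpy(dtype=float)
        if len(vals):
            out[label] = log2_counts(vals, pseudo=pseudo)
    return out
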