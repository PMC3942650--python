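"""One-way ANOVA with Scheffé post-hoc comparisons, plus derived summaries.

The statistical layer mirrors how age-group comparisons are reported in
auditory aging studies: an independent one-way ANOVA per frequency (or per
wave × frequency, or per densitometric index), followed by Scheffé's
all-contrasts-protected pairwise test, with significance starred at
p < 0.05 / 0.01 / 0.001.  ANOVA is available both from raw per-subject
values and from published summary statistics (mean, SD, n per group); the
two forms are algebraically identical when fed the same data.

No multiple-testing correction is applied across frequencies/waves by
default (each ANOVA is reported independently); a Bonferroni option exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group for one metric."""

    label: str
    n: int
    mean: float
    sd: float
    metric: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError("group summaries need n >= 2")
        if self.sd < 0:
            raise InputError("sd must be non-negative")


@dataclass(frozen=True)
class PairwiseResult:
    """One Scheffé contrast between two groups."""

    pair: Tuple[str, str]
    mean_diff: float
    statistic: float      # squared contrast / (MSW · (1/ni + 1/nj))
    critical: float       # (k−1) · F_crit(α; k−1, N−k)
    significant: bool
    alpha: float


@dataclass
class GroupComparison:
    """Omnibus one-way ANOVA result, optionally with post-hoc contrasts."""

    F: float
    df1: int
    df2: int
    p: float
    ms_within: float = float("nan")
    group_labels: Tuple[str, ...] = ()
    posthoc: List[PairwiseResult] = field(default_factory=list)

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def _check_groups(groups: Sequence[Sequence[float]]) -> List[np.ndarray]:
    if len(groups) < 2:
        raise InputError("ANOVA needs at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise InputError("every group needs at least two observations")
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise InputError("non-finite observations")
    return arrs


def anova_oneway(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None
) -> GroupComparison:
    """One-way fixed-effects ANOVA from raw per-subject values.

    F = MS_between / MS_within with the standard sums of squares; the
    p-value comes from the F(k−1, N−k) distribution.  Zero within-group
    variance with unequal means yields the F = +inf sentinel with p = 0.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    ns = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    grand = float(np.concatenate(arrs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df1, df2 = k - 1, int(ns.sum()) - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        f_val = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_val = ms_between / ms_within
        p = float(stats.f.sf(f_val, df1, df2))
    return GroupComparison(
        F=f_val, df1=df1, df2=df2, p=p, ms_within=ms_within,
        group_labels=tuple(labels) if labels else tuple(f"g{i}" for i in range(k)),
    )


def anova_from_summary(summaries: Sequence[GroupSummary]) -> GroupComparison:
    """One-way ANOVA from per-group (mean, SD, n) summary statistics.

    Algebraically identical to :func:`anova_oneway` when the summaries are
    computed from the same raw data: SS_within = Σ (n_i − 1) s_i² and
    SS_between = Σ n_i (m_i − grand mean)².
    """
    if len(summaries) < 2:
        raise InputError("ANOVA needs at least two groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    metrics = {s.metric for s in summaries if s.metric}
    if len(metrics) > 1:
        raise InputError(f"summaries mix metrics: {sorted(metrics)}")
    grand = float(np.sum(ns * means) / ns.sum())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df1, df2 = len(summaries) - 1, int(ns.sum()) - len(summaries)
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        f_val = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_val = ms_between / ms_within
        p = float(stats.f.sf(f_val, df1, df2))
    return GroupComparison(
        F=f_val, df1=df1, df2=df2, p=p, ms_within=ms_within,
        group_labels=tuple(s.label for s in summaries),
    )


def summarize(values: Sequence[float], label: str = "", metric: str = "") -> GroupSummary:
    """Mean ± SD (n−1 denominator) summary of one group's raw values."""
    a = np.asarray(values, dtype=float)
    return GroupSummary(label=label, n=a.size, mean=float(a.mean()),
                        sd=float(a.std(ddof=1)), metric=metric)


def scheffe(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> List[PairwiseResult]:
    """Scheffé post-hoc pairwise comparisons after a one-way ANOVA.

    Pair (i, j) is significant iff

        (ȳ_i − ȳ_j)² / (MS_within · (1/n_i + 1/n_j)) > (k−1) · F_crit(α; k−1, N−k)

    which protects all contrasts simultaneously; no pair can be significant
    when the omnibus F does not exceed its critical value.
    """
    arrs = _check_groups(groups)
    omni = anova_oneway(groups, labels)
    labs = omni.group_labels
    k = len(arrs)
    f_crit = float(stats.f.isf(alpha, omni.df1, omni.df2))
    critical = (k - 1) * f_crit
    out: List[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrs[i].mean() - arrs[j].mean())
            if omni.ms_within == 0:
                statistic = math.inf if diff != 0 else 0.0
            else:
                statistic = diff**2 / (omni.ms_within * (1 / arrs[i].size + 1 / arrs[j].size))
            out.append(
                PairwiseResult(
                    pair=(labs[i], labs[j]),
                    mean_diff=diff,
                    statistic=statistic,
                    critical=critical,
                    significant=statistic > critical,
                    alpha=alpha,
                )
            )
    return out


def anova_with_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Omnibus ANOVA plus Scheffé contrasts in one call."""
    omni = anova_oneway(groups, labels)
    omni.posthoc = scheffe(groups, labels, alpha)
    return omni


def threshold_shift(reference: GroupSummary, other: GroupSummary) -> float:
    """Mean threshold elevation of ``other`` relative to ``reference`` (dB)."""
    if reference.metric and other.metric and reference.metric != other.metric:
        raise InputError(
            f"metric mismatch: {reference.metric!r} vs {other.metric!r}"
        )
    return other.mean - reference.mean


def percent_variation(reference_mean: float, other_mean: float) -> float:
    """Percent change of ``other_mean`` relative to ``reference_mean``.

    Returns NaN (reported as missing) when the reference mean is zero.
    """
    if reference_mean == 0:
        return float("nan")
    return 100.0 * (other_mean - reference_mean) / reference_mean


def null_rejection_rate(
    n_groups: int = 3,
    n_per_group: int = 8,
    n_replicates: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of the omnibus ANOVA under the null.

    Draws ``n_replicates`` datasets of ``n_groups`` × ``n_per_group``
    observations from a single normal distribution (the null model in which
    all age effects are zero), runs the one-way ANOVA on each, and returns
    the fraction rejected at ``alpha``.  Vectorised over replicates.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_replicates, n_groups, n_per_group))
    gm = x.mean(axis=2)                               # (reps, k)
    grand = x.mean(axis=(1, 2), keepdims=True)
    ss_between = n_per_group * ((gm - grand[:, :, 0]) ** 2).sum(axis=1)
    ss_within = ((x - gm[:, :, None]) ** 2).sum(axis=(1, 2))
    df1 = n_groups - 1
    df2 = n_groups * (n_per_group - 1)
    f_vals = (ss_between / df1) / (ss_within / df2)
    f_crit = stats.f.isf(alpha, df1, df2)
    return float(np.mean(f_vals > f_crit))


# ---------------------------------------------------------------------------
# Publication-style tables from tidy feature frames
# ---------------------------------------------------------------------------

def anova_table(
    df: pd.DataFrame,
    value: str,
    group_col: str = "group",
    row_col: Optional[str] = "wave",
    col_col: str = "freq_khz",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run an independent one-way ANOVA per (row × column) cell of a tidy frame.

    Returns ``(table, posthoc)``: a wide table whose cells hold
    ``"F=… df=(a,b) <stars>"`` and a long per-pair Scheffé table.  Rows with
    missing values (e.g. no-response thresholds) are dropped with their
    count recorded in ``table.attrs["n_dropped"]``.
    """
    work = df.dropna(subset=[value])
    n_dropped = len(df) - len(work)
    a = alpha
    cells = []
    posthoc_rows = []
    row_levels = [None] if row_col is None else sorted(work[row_col].unique())
    col_levels = sorted(work[col_col].unique())
    for r in row_levels:
        sub_r = work if r is None else work[work[row_col] == r]
        for c in col_levels:
            sub = sub_r[sub_r[col_col] == c]
            labels = sorted(sub[group_col].unique())
            groups = [sub.loc[sub[group_col] == g, value].to_numpy() for g in labels]
            if len(groups) < 2 or any(len(g) < 2 for g in groups):
                continue
            eff_alpha = a / (len(row_levels) * len(col_levels)) if bonferroni else a
            comp = anova_with_posthoc(groups, labels, alpha=eff_alpha)
            cells.append({
                "row": "all" if r is None else r, "col": c, "F": comp.F,
                "df1": comp.df1, "df2": comp.df2, "p": comp.p, "stars": comp.stars,
            })
            for ph in comp.posthoc:
                posthoc_rows.append({
                    "row": "all" if r is None else r, "col": c,
                    "pair": "-".join(ph.pair), "mean_diff": ph.mean_diff,
                    "statistic": ph.statistic, "critical": ph.critical,
                    "significant": ph.significant, "alpha": ph.alpha,
                })
    long = pd.DataFrame(cells)
    if long.empty:
        table = pd.DataFrame()
    else:
        long["cell"] = long.apply(
            lambda x: f"F({x.df1},{x.df2})={x.F:.2f} {x.stars}", axis=1
        )
        table = long.pivot(index="row", columns="col", values="cell")
    table.attrs["n_dropped"] = n_dropped
    return table, pd.DataFrame(posthoc_rows)
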