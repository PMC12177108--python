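"""Cohort-level statistics on a per-subject metrics table.

Implements the study-style battery: Shapiro-Wilk-routed two-group
comparisons (Welch t or Mann-Whitney U), paired pre/post comparisons
(paired t or Wilcoxon signed-rank), Spearman correlations against a
covariate with Hochberg step-up adjustment, and a binary stratification
(e.g. gas trapping) applied metric by metric.

The cohort table is a pandas DataFrame with one row per (subject,
condition) and columns for the group label, condition label, metrics and
covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidParameterError, UndefinedMetricError

NORMALITY_ALPHA = 0.05
EXACT_N_MAX = 25


@dataclass
class StatResult:
    """Outcome of one hypothesis test with route and summaries."""

    test_name: str
    statistic: float
    p_value: float
    metric: str
    p_adjusted: float | None = None
    summaries: dict = field(default_factory=dict)
    reliable: bool = True
    notes: list[str] = field(default_factory=list)


def _summary(x: np.ndarray, parametric: bool) -> str:
    if parametric:
        return f"{np.mean(x):.3g} ± {np.std(x, ddof=1):.3g}"
    p25, p50, p75 = np.percentile(x, [25, 50, 75])
    return f"{p50:.3g} ({p25:.3g}–{p75:.3g})"


def _is_normal(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return np.unique(combined).size < combined.size


def _two_groups(
    table: pd.DataFrame, metric: str, group_col: str, groups: tuple | None
) -> tuple[np.ndarray, np.ndarray, tuple]:
    labels = groups or tuple(pd.unique(table[group_col]))
    if len(labels) != 2:
        raise InvalidParameterError(f"need exactly two groups, got {labels}")
    x = table.loc[table[group_col] == labels[0], metric].dropna().to_numpy(float)
    y = table.loc[table[group_col] == labels[1], metric].dropna().to_numpy(float)
    return x, y, labels


def route_and_compare(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    groups: tuple | None = None,
    alpha_normality: float = NORMALITY_ALPHA,
    equal_var: bool = False,
    route: str = "auto",
) -> StatResult:
    """Two-group unpaired comparison routed by Shapiro-Wilk normality.

    Both groups normal at the gate's alpha -> two-sample t-test (Welch by
    default); otherwise Mann-Whitney U (exact when both n <= 25 without
    ties, tie-corrected normal approximation otherwise). A zero-variance
    group routes to Mann-Whitney with a note. ``route`` overrides the
    normality gate ('t' or 'mwu').
    """
    if route not in ("auto", "t", "mwu"):
        raise InvalidParameterError(f"unknown route {route!r}")
    x, y, labels = _two_groups(table, metric, group_col, groups)
    if min(x.size, y.size) < 3:
        raise InvalidParameterError("need >= 3 subjects per group")
    notes = []
    zero_var = np.ptp(x) == 0 or np.ptp(y) == 0
    if zero_var and route != "mwu":
        notes.append("zero-variance group: routed to Mann-Whitney U")
        warnings.warn(notes[-1])
        normal = False
    elif route == "auto":
        normal = _is_normal(x, alpha_normality) and _is_normal(y, alpha_normality)
    else:
        normal = route == "t"
    if normal:
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        name = "t-test (Welch)" if not equal_var else "t-test (pooled)"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        method = (
            "exact"
            if max(x.size, y.size) <= EXACT_N_MAX and not _has_ties(x, y)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        name = f"Mann-Whitney U ({method})"
        stat, p = float(res.statistic), float(res.pvalue)
    return StatResult(
        name,
        stat,
        p,
        metric,
        summaries={
            str(labels[0]): _summary(x, normal),
            str(labels[1]): _summary(y, normal),
        },
        notes=notes,
    )


def paired_compare(
    table: pd.DataFrame,
    metric: str,
    subject_col: str = "subject",
    condition_col: str = "condition",
    conditions: tuple = ("pre", "post"),
    alpha_normality: float = NORMALITY_ALPHA,
) -> StatResult:
    """Paired pre/post comparison routed by normality of the differences.

    Only subjects present in both conditions enter. All-zero differences
    give p = 1 with a warning; constant non-zero differences route to the
    Wilcoxon signed-rank test (the paired t is undefined at zero variance).
    """
    wide = table.pivot_table(index=subject_col, columns=condition_col, values=metric)
    wide = wide.dropna(subset=list(conditions))
    if len(wide) < 3:
        raise InvalidParameterError("need >= 3 complete pairs")
    pre = wide[conditions[0]].to_numpy(float)
    post = wide[conditions[1]].to_numpy(float)
    diff = post - pre
    notes = []
    summaries = {
        conditions[0]: _summary(pre, True),
        conditions[1]: _summary(post, True),
    }
    if np.all(diff == 0):
        notes.append("all paired differences are zero")
        warnings.warn(notes[-1])
        return StatResult("paired (degenerate)", 0.0, 1.0, metric, summaries=summaries, notes=notes)
    if np.ptp(diff) == 0:
        notes.append("constant differences: routed to Wilcoxon signed-rank")
        normal = False
    else:
        normal = _is_normal(diff, alpha_normality)
    if normal:
        res = stats.ttest_rel(post, pre)
        name = "paired t-test"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        nz = diff[diff != 0]
        method = (
            "exact"
            if nz.size <= EXACT_N_MAX and np.unique(np.abs(nz)).size == nz.size
            else "approx"
        )
        res = stats.wilcoxon(post, pre, method=method)
        name = f"Wilcoxon signed-rank ({method})"
        stat, p = float(res.statistic), float(res.pvalue)
        summaries = {c: _summary(v, False) for c, v in ((conditions[0], pre), (conditions[1], post))}
    return StatResult(name, stat, p, metric, summaries=summaries, notes=notes)


def hochberg_adjust(p_values: np.ndarray) -> np.ndarray:
    """Hochberg step-up adjusted p-values for one family."""
    p_values = np.asarray(p_values, dtype=float)
    return multipletests(p_values, method="simes-hochberg")[1]


def spearman_family(
    table: pd.DataFrame,
    metrics: list[str],
    covariate: str,
) -> list[StatResult]:
    """Spearman correlations of each metric with a covariate, adjusted as
    one Hochberg family across the supplied metric list.

    Uses midrank handling of ties with asymptotic p-values.
    """
    results = []
    for metric in metrics:
        sub = table[[metric, covariate]].dropna()
        if len(sub) < 5:
            raise InvalidParameterError(f"need >= 5 complete observations for {metric}")
        cov = sub[covariate].to_numpy(float)
        if np.ptp(cov) == 0:
            raise UndefinedMetricError("constant covariate: correlation undefined")
        rho, p = stats.spearmanr(sub[metric].to_numpy(float), cov)
        results.append(
            StatResult("Spearman", float(rho), float(p), metric, summaries={"n": len(sub)})
        )
    adjusted = hochberg_adjust([r.p_value for r in results])
    for r, adj in zip(results, adjusted):
        r.p_adjusted = float(adj)
    return results


def stratify_binary(
    table: pd.DataFrame,
    flag_col: str,
    metrics: list[str],
    **kwargs,
) -> list[StatResult]:
    """Compare each metric between the two strata of a binary flag.

    Results for strata smaller than 3 subjects are flagged unreliable
    (computed with the rank test when possible, NaN otherwise).
    """
    flags = table[flag_col].astype(bool)
    n_true, n_false = int(flags.sum()), int((~flags).sum())
    if n_true == 0 or n_false == 0:
        raise InvalidParameterError("both strata must be nonempty")
    results = []
    for metric in metrics:
        if min(n_true, n_false) < 3:
            x = table.loc[flags, metric].dropna().to_numpy(float)
            y = table.loc[~flags, metric].dropna().to_numpy(float)
            if min(x.size, y.size) >= 1 and max(x.size, y.size) >= 2:
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                r = StatResult("Mann-Whitney U (asymptotic)", float(res.statistic),
                               float(res.pvalue), metric)
            else:
                r = StatResult("untestable", float("nan"), float("nan"), metric)
            r.reliable = False
            r.notes.append(f"stratum sizes {n_true}/{n_false} < 3: unreliable")
        else:
            r = route_and_compare(table, metric, group_col=flag_col, groups=(True, False), **kwargs)
        results.append(r)
    return results


def results_table(results: list[StatResult]) -> pd.DataFrame:
    """Flatten StatResults into a tidy DataFrame for CSV/markdown export."""
    rows = []
    for r in results:
        row = {
            "metric": r.metric,
            "test": r.test_name,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "reliable": r.reliable,
        }
        for k, v in r.summaries.items():
            row[f"summary_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
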