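"""Statistical workflow for synapse-density comparisons.

The workflow mirrors common practice for small neuropathology cohorts:

* a Shapiro-Wilk normality gate decides between a two-sided Welch t-test
  (means) and a two-sided Mann-Whitney U test (medians) for two groups;
* Holm-Sidak step-down correction for families of pairwise p-values;
* one-way ANOVA with Tukey HSD for overall group effects;
* two-way fixed-effects ANOVA (cohort x distance class) with a
  median-centred Levene homogeneity check, followed by the Games-Howell
  post hoc test, which tolerates unequal variances by combining
  Welch-Satterthwaite degrees of freedom with the studentized-range
  distribution;
* one-way repeated-measures ANOVA across the five distance classes with an
  omega-squared effect size and Holm-Sidak-adjusted paired post hocs;
* Pearson correlation of neuropathological trait counts with densities.

Pairwise results serialize to a fixed schema: group pair, mean difference,
standard error, T-value, degrees of freedom, p-value, upper and lower
confidence limits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "normality_gate",
    "compare_groups",
    "pairwise_holm_sidak",
    "anova_oneway_tukey",
    "anova_twoway_levene",
    "games_howell",
    "rm_anova_omega",
    "correlate_traits",
    "pairwise_table",
]

PAIRWISE_COLUMNS = [
    "groups",
    "mean_difference",
    "standard_error",
    "t_value",
    "df",
    "p_value",
    "ci_upper",
    "ci_lower",
]


@dataclass
class StatResult:
    """One statistical comparison.

    ``df`` may be fractional (Welch-Satterthwaite); ``effect_size`` holds
    omega-squared for repeated-measures ANOVA; the mean-difference /
    standard-error / CI fields are populated for pairwise results.
    """

    test: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    groups: tuple[str, ...] = ()
    adjusted_p: float | None = None
    effect_size: float | None = None
    mean_difference: float | None = None
    standard_error: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.p_value <= 1 + 1e-12:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        self.p_value = float(min(max(self.p_value, 0.0), 1.0))

    def to_row(self) -> dict:
        row = asdict(self)
        row["groups"] = " : ".join(self.groups)
        return row


def pairwise_table(results: Iterable[StatResult]) -> pd.DataFrame:
    """Serialize pairwise results to the fixed output schema."""
    rows = []
    for r in results:
        rows.append(
            {
                "groups": " : ".join(r.groups),
                "mean_difference": r.mean_difference,
                "standard_error": r.standard_error,
                "t_value": r.statistic,
                "df": r.df,
                "p_value": r.adjusted_p if r.adjusted_p is not None else r.p_value,
                "ci_upper": r.ci_upper,
                "ci_lower": r.ci_lower,
            }
        )
    return pd.DataFrame(rows, columns=PAIRWISE_COLUMNS)


def normality_gate(sample: Sequence[float], alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate: 'parametric' iff normality is not rejected at alpha."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"normality gate needs n >= 3, got n = {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("normality gate undefined for a zero-variance sample")
    _, p = sps.shapiro(x)
    return "parametric" if p >= alpha else "nonparametric"


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    gate: str | None = None,
) -> StatResult:
    """Two-sided two-group comparison chosen by the normality gate.

    Parametric branch: Welch (unequal-variance) t-test on means.
    Nonparametric branch: Mann-Whitney U on medians (exact for small
    tie-free samples, normal approximation with tie correction otherwise).
    With ``gate=None`` both samples are gated and the parametric branch is
    taken only if neither rejects.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if gate is None:
        gates = {normality_gate(a), normality_gate(b)}
        gate = "parametric" if gates == {"parametric"} else "nonparametric"
    if gate == "parametric":
        res = sps.ttest_ind(a, b, equal_var=False)
        return StatResult(
            test="welch_t",
            statistic=float(res.statistic),
            df=float(res.df),
            p_value=float(res.pvalue),
            mean_difference=float(a.mean() - b.mean()),
            standard_error=float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)),
        )
    if gate == "nonparametric":
        method = "exact" if max(a.size, b.size) <= 20 else "asymptotic"
        try:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:  # ties -> exact unavailable
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return StatResult(
            test="mann_whitney_u",
            statistic=float(res.statistic),
            df=None,
            p_value=float(res.pvalue),
            mean_difference=float(np.median(a) - np.median(b)),
        )
    raise ValueError(f"unknown gate {gate!r}")


def pairwise_holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def anova_oneway_tukey(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[StatResult]:
    """One-way ANOVA followed by a Tukey HSD pairwise table.

    Returns the omnibus F result first, then one pairwise result per group
    pair with mean difference and Tukey confidence limits.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrays))]
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    results = [
        StatResult(
            test="anova_oneway",
            statistic=float(f),
            df=(k - 1, n_total - k),
            p_value=float(p),
            groups=tuple(labels),
        )
    ]
    tukey = sps.tukey_hsd(*arrays)
    ci = tukey.confidence_interval(confidence_level=1 - alpha)
    for i, j in combinations(range(k), 2):
        results.append(
            StatResult(
                test="tukey_hsd",
                statistic=float(tukey.statistic[i, j]),
                df=float(n_total - k),
                p_value=float(tukey.pvalue[i, j]),
                groups=(labels[i], labels[j]),
                mean_difference=float(arrays[i].mean() - arrays[j].mean()),
                ci_lower=float(ci.low[i, j]),
                ci_upper=float(ci.high[i, j]),
            )
        )
    return results


def anova_twoway_levene(
    table: pd.DataFrame,
    value: str = "density",
    factor_a: str = "cohort",
    factor_b: str = "distance_class",
) -> dict[str, StatResult]:
    """Two-way fixed-effects ANOVA with a Levene homogeneity check.

    Fits ``value ~ A * B`` by OLS and reports type-II F tests for both main
    effects and the interaction, plus a Brown-Forsythe Levene test
    (median-centred) of variance homogeneity across ``factor_a`` groups.
    """
    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    data = table[[value, factor_a, factor_b]].dropna().copy()
    data.columns = ["y", "A", "B"]
    model = ols("y ~ C(A) * C(B)", data=data).fit()
    aov = anova_lm(model, typ=2)
    if aov.drop(index="Residual")["F"].isna().any():
        raise ValueError(
            "degenerate two-way design (constant response or empty cells); "
            "F statistics are undefined"
        )

    def _res(row_name: str, label: str) -> StatResult:
        row = aov.loc[row_name]
        return StatResult(
            test=f"anova_twoway_{label}",
            statistic=float(row["F"]),
            df=(float(row["df"]), float(aov.loc["Residual", "df"])),
            p_value=float(row["PR(>F)"]),
            groups=(factor_a, factor_b),
        )

    groups_a = [g["y"].to_numpy() for _, g in data.groupby("A")]
    lev_stat, lev_p = sps.levene(*groups_a, center="median")
    return {
        factor_a: _res("C(A)", factor_a),
        factor_b: _res("C(B)", factor_b),
        "interaction": _res("C(A):C(B)", "interaction"),
        "levene": StatResult(
            test="levene_median",
            statistic=float(lev_stat),
            df=(len(groups_a) - 1, len(data) - len(groups_a)),
            p_value=float(lev_p),
            groups=(factor_a,),
        ),
    }


def games_howell(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Games-Howell post hoc test for all group pairs under unequal variances.

    For each pair: mean difference, SE = sqrt(s1^2/n1 + s2^2/n2),
    Welch-Satterthwaite df, T = |difference| / SE, and p from the
    studentized-range distribution of q = T * sqrt(2) with k groups;
    confidence limits use the same quantile.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(k)]
    means = [a.mean() for a in arrays]
    variances = [a.var(ddof=1) for a in arrays]
    ns = [a.size for a in arrays]

    results = []
    for i, j in combinations(range(k), 2):
        vi, vj = variances[i] / ns[i], variances[j] / ns[j]
        se = np.sqrt(vi + vj)
        diff = means[i] - means[j]
        if vi + vj > 0:
            df = (vi + vj) ** 2 / (vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1))
            t = abs(diff) / se
            p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
            q_crit = sps.studentized_range.ppf(1 - alpha, k, df)
            half_width = q_crit / np.sqrt(2.0) * se
        else:  # degenerate: identical constant groups
            df, t, p, half_width = float(ns[i] + ns[j] - 2), 0.0, 1.0, 0.0
        results.append(
            StatResult(
                test="games_howell",
                statistic=float(t),
                df=float(df),
                p_value=p,
                groups=(labels[i], labels[j]),
                mean_difference=float(diff),
                standard_error=float(se),
                ci_lower=float(diff - half_width),
                ci_upper=float(diff + half_width),
            )
        )
    return results


def rm_anova_omega(
    data: pd.DataFrame | np.ndarray,
    subject: str = "astrocyte_id",
    within: str = "distance_class",
    value: str = "density",
) -> tuple[StatResult, list[StatResult]]:
    """One-way repeated-measures ANOVA with omega-squared and paired post hocs.

    Accepts a wide subjects-by-conditions array or a long table. F uses the
    within-subject error term; the effect size is
    omega^2 = df_t (MS_t - MS_e) / (SS_total + MS_subject), reported as
    computed (it can be slightly negative under the null). Post hoc paired
    t-tests over all condition pairs are Holm-Sidak adjusted.
    """
    if isinstance(data, pd.DataFrame):
        wide = data.pivot(index=subject, columns=within, values=value)
        cond_labels = [str(c) for c in wide.columns]
        y = wide.to_numpy(dtype=float)
    else:
        y = np.asarray(data, dtype=float)
        cond_labels = [f"c{i}" for i in range(y.shape[1])]
    if np.isnan(y).any():
        raise ValueError("repeated-measures table must be complete (no missing cells)")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")

    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_subject = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_treat = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_error = ss_total - ss_subject - ss_treat
    df_treat, df_error = k - 1, (k - 1) * (n - 1)
    ms_treat, ms_error = ss_treat / df_treat, ss_error / df_error
    ms_subject = ss_subject / (n - 1)
    f = ms_treat / ms_error if ms_error > 0 else 0.0
    p = float(sps.f.sf(f, df_treat, df_error)) if ms_error > 0 else 1.0
    omega2 = (df_treat * (ms_treat - ms_error)) / (ss_total + ms_subject)

    omnibus = StatResult(
        test="rm_anova",
        statistic=float(f),
        df=(float(df_treat), float(df_error)),
        p_value=p,
        groups=tuple(cond_labels),
        effect_size=float(omega2),
    )

    posthoc: list[StatResult] = []
    raw_p = []
    for i, j in combinations(range(k), 2):
        d = y[:, i] - y[:, j]
        if np.ptp(d) == 0:
            t, pv = 0.0, 1.0
        else:
            t, pv = sps.ttest_rel(y[:, i], y[:, j])
        raw_p.append(float(pv))
        se = d.std(ddof=1) / np.sqrt(n)
        posthoc.append(
            StatResult(
                test="paired_t",
                statistic=float(t),
                df=float(n - 1),
                p_value=float(pv),
                groups=(cond_labels[i], cond_labels[j]),
                mean_difference=float(d.mean()),
                standard_error=float(se),
            )
        )
    adjusted = pairwise_holm_sidak(raw_p)
    for r, ap in zip(posthoc, adjusted):
        r.adjusted_p = float(ap)
    return omnibus, posthoc


def correlate_traits(
    traits: pd.DataFrame,
    densities: pd.DataFrame,
    trait_columns: Sequence[str] | None = None,
    case_column: str = "case",
    diagnosis_column: str = "diagnosis",
    density_column: str = "density",
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate per-case neuropathological trait counts with densities.

    Joins the trait table with per-case densities and reports, per
    diagnosis cohort and per trait, the correlation coefficient and its
    two-sided p-value. Ordinal grades (e.g. neuropil-thread scores 0-5)
    enter as numeric values; ``method='spearman'`` switches to rank
    correlation.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    merged = traits.merge(densities[[case_column, density_column]], on=case_column)
    if trait_columns is None:
        trait_columns = [
            c
            for c in traits.columns
            if c not in (case_column, diagnosis_column)
            and np.issubdtype(merged[c].dtype, np.number)
        ]
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr
    rows = []
    for diagnosis, grp in merged.groupby(diagnosis_column):
        for trait in trait_columns:
            x = grp[trait].to_numpy(dtype=float)
            y = grp[density_column].to_numpy(dtype=float)
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                res = corr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "diagnosis": diagnosis,
                    "trait": trait,
                    "r": r,
                    "p_value": p,
                    "n": len(x),
                    "method": method,
                }
            )
    return pd.DataFrame(rows)
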