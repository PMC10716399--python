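"""Gated group statistics for per-subject measures.

The decision rules mirror a conventional SPSS-style behavioural workflow:

* normality is gated by the Shapiro-Wilk test in every group (p >= .05 in
  all groups -> parametric, else nonparametric);
* two-sample comparisons use Student's t when Levene's test accepts
  variance homogeneity, Welch's t otherwise, and the Mann-Whitney U test
  when the normality gate fails;
* paired comparisons use the paired t-test or the Wilcoxon signed-rank
  test, gated on the difference scores;
* the day-course of a measure is analysed by a two-way mixed ANOVA
  (group between, day within) with Mauchly's sphericity test,
  Greenhouse-Geisser correction of the within dfs where sphericity fails,
  and Tukey-HSD post-hoc contrasts;
* subgroup analyses: Pearson correlations with age, one-way ANOVAs over
  pre-trial media-consumption tertiles (cut points 15 and 30 h/week,
  left-closed bins) and over preferred-content groups, and gender /
  group x gender comparisons.

Every result records which assumption gates were evaluated and how they
decided.  Effect sizes are Cohen's d with pooled SD, signed as
(NOTV - TV) / s_p so a TV advantage yields a negative d.  Descriptive
confidence intervals use the z formula mean +/- 1.96 * SD / sqrt(n);
intervals around mean differences use t quantiles.  No multiplicity
correction is applied across behavioural endpoints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DataIntegrityError, MissingDataError

ALPHA = 0.05
Z_95 = 1.959963984540054
GROUP_ORDER = ("NOTV", "TV")  # difference and d are first minus second


@dataclass
class StatResult:
    """One statistical comparison with its assumption log."""

    test_name: str
    statistic: float
    df: float | tuple | None
    p_value: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    assumptions_log: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": _jsonable(self.statistic),
            "df": _jsonable(self.df),
            "p_value": _jsonable(self.p_value),
            "effect_size": _jsonable(self.effect_size),
            "effect_size_name": self.effect_size_name,
            "ci_low": _jsonable(self.ci_low),
            "ci_high": _jsonable(self.ci_high),
            "assumptions_log": {k: _jsonable(v) for k, v in self.assumptions_log.items()},
        }
        if self.extra:
            d["extra"] = {k: _jsonable(v) for k, v in self.extra.items()}
        return d


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


# ---------------------------------------------------------------------------
# gates
# ---------------------------------------------------------------------------


def normality_gate(groups: dict[str, np.ndarray]) -> tuple[str, dict]:
    """Shapiro-Wilk gate: 'parametric' iff p >= .05 in every group.

    Groups with fewer than 3 values or zero variance make the gate
    inconclusive; the decision then defaults to 'nonparametric' with a
    warning recorded in the log.
    """
    log: dict = {"gate": "shapiro_wilk", "alpha": ALPHA, "per_group": {}}
    decision = "parametric"
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        if len(values) < 3:
            log["per_group"][name] = {"warning": "n < 3, gate inconclusive"}
            decision = "nonparametric"
            continue
        if np.ptp(values) == 0:
            log["per_group"][name] = {"warning": "degenerate data (zero variance)"}
            decision = "nonparametric"
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.shapiro(values)
        log["per_group"][name] = {"W": float(stat), "p": float(p)}
        if p < ALPHA:
            decision = "nonparametric"
    log["decision"] = decision
    return decision, log


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d of a - b."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(sp2))


def descriptive_ci(values: np.ndarray) -> tuple[float, float]:
    """The z-formula descriptive interval: mean +/- 1.96 * SD / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    half = Z_95 * values.std(ddof=1) / math.sqrt(len(values))
    return float(values.mean() - half), float(values.mean() + half)


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------


def compare_groups(
    table: pd.DataFrame,
    measure: str,
    group_col: str = "group",
    order: tuple[str, str] = GROUP_ORDER,
) -> StatResult:
    """Independent two-sample comparison of ``measure`` between two groups.

    Route: normality gate -> (Levene -> Student or Welch t) or
    Mann-Whitney U.  The mean difference, its t-based 95% CI and pooled-SD
    Cohen's d are reported in ``order[0] - order[1]`` direction.
    """
    present = [g for g in order if g in set(table[group_col])]
    if len(present) < 2:
        raise MissingDataError(f"need both groups {order}, found {present}")
    a = table.loc[table[group_col] == order[0], measure].dropna().to_numpy(float)
    b = table.loc[table[group_col] == order[1], measure].dropna().to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise MissingDataError("one group has no values")

    decision, log = normality_gate({order[0]: a, order[1]: b})
    diff = float(a.mean() - b.mean())
    d = _cohens_d(a, b)

    if decision == "parametric":
        lev_stat, lev_p = stats.levene(a, b)
        log["levene"] = {"W": float(lev_stat), "p": float(lev_p)}
        equal_var = lev_p >= ALPHA
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        df = float(res.df)
        ci = res.confidence_interval(0.95)
        result = StatResult(
            test_name="student_t" if equal_var else "welch_t",
            statistic=float(res.statistic),
            df=df,
            p_value=float(res.pvalue),
            effect_size=d,
            effect_size_name="cohens_d",
            ci_low=float(ci.low),
            ci_high=float(ci.high),
            assumptions_log=log,
            extra={"mean_difference": diff},
        )
    else:
        if np.ptp(np.concatenate([a, b])) == 0:
            result = StatResult(
                test_name="mann_whitney_u",
                statistic=float(len(a) * len(b) / 2),
                df=None,
                p_value=1.0,
                effect_size=0.0,
                effect_size_name="cohens_d",
                assumptions_log=log,
                extra={"mean_difference": 0.0, "warning": "degenerate data"},
            )
        else:
            method = "exact" if (len(a) <= 20 and len(b) <= 20) else "asymptotic"
            try:
                res = stats.mannwhitneyu(a, b, method=method)
            except ValueError:  # ties with exact method
                res = stats.mannwhitneyu(a, b, method="asymptotic")
            result = StatResult(
                test_name="mann_whitney_u",
                statistic=float(res.statistic),
                df=None,
                p_value=float(res.pvalue),
                effect_size=d,
                effect_size_name="cohens_d",
                assumptions_log=log,
                extra={"mean_difference": diff},
            )
    result.extra["n"] = {order[0]: len(a), order[1]: len(b)}
    result.extra["descriptive_ci"] = {
        order[0]: descriptive_ci(a),
        order[1]: descriptive_ci(b),
    }
    return result


def paired_compare(pre: np.ndarray, post: np.ndarray) -> StatResult:
    """Within-subject pre/post comparison, gated on the difference scores."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise DataIntegrityError("pre and post must have equal length")
    keep = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[keep], post[keep]
    if len(pre) < 3:
        raise MissingDataError("paired comparison needs n >= 3 complete pairs")
    diffs = post - pre
    decision, log = normality_gate({"differences": diffs})

    if np.ptp(diffs) == 0:
        change = float(diffs.mean())
        return StatResult(
            test_name="paired_t" if change == 0 else "degenerate_shift",
            statistic=0.0 if change == 0 else math.inf,
            df=len(diffs) - 1,
            p_value=1.0 if change == 0 else 0.0,
            assumptions_log=log,
            extra={"mean_change": change, "n": len(diffs)},
        )
    if decision == "parametric":
        res = stats.ttest_rel(post, pre)
        ci = res.confidence_interval(0.95)
        sd = diffs.std(ddof=1)
        return StatResult(
            test_name="paired_t",
            statistic=float(res.statistic),
            df=float(res.df),
            p_value=float(res.pvalue),
            effect_size=float(diffs.mean() / sd),
            effect_size_name="cohens_dz",
            ci_low=float(ci.low),
            ci_high=float(ci.high),
            assumptions_log=log,
            extra={"mean_change": float(diffs.mean()), "n": len(diffs)},
        )
    mode = "exact" if len(diffs) <= 20 and not np.any(diffs == 0) else "approx"
    res = stats.wilcoxon(diffs, method=mode, correction=(mode == "approx"))
    return StatResult(
        test_name="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        assumptions_log=log,
        extra={"mean_change": float(diffs.mean()), "n": len(diffs)},
    )


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    within: str = "day",
    subject: str = "subject_id",
    between: str = "group",
) -> dict[str, StatResult]:
    """Two-way mixed ANOVA with sphericity gate and Tukey post-hocs.

    Returns results keyed 'within', 'between', 'interaction',
    'posthoc_between' and 'posthoc_within'; within-subject dfs carry the
    Greenhouse-Geisser epsilon when Mauchly's test rejects sphericity.
    """
    data = table.dropna(subset=[dv]).copy()
    if data[within].nunique() < 2 or data[between].nunique() < 2:
        raise DataIntegrityError("mixed ANOVA needs >= 2 levels of both factors")
    # keep complete cases only (subjects observed on all within levels)
    n_levels = data[within].nunique()
    complete = data.groupby(subject)[within].nunique() == n_levels
    data = data[data[subject].map(complete)]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=data, dv=dv, within=within, subject=subject, between=between,
            correction=True,
        )
        spher = pg.sphericity(data, dv=dv, within=within, subject=subject)
    aov = aov.set_index("Source")
    eps = float(aov.loc[within, "eps"])
    sphericity_ok = bool(spher.spher)
    log = {
        "gate": "mauchly",
        "W": float(spher.W),
        "p": float(spher.pval),
        "sphericity": sphericity_ok,
        "greenhouse_geisser_eps": eps,
        "gg_applied": not sphericity_ok,
        "n_complete_subjects": int(data[subject].nunique()),
    }

    def row_result(source: str, corrected: bool) -> StatResult:
        row = aov.loc[source]
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        p = float(row["p_unc"])
        if corrected and not sphericity_ok:
            df1, df2 = df1 * eps, df2 * eps
            p_gg = row.get("p_GG_corr", math.nan)
            if not math.isnan(p_gg):
                p = float(p_gg)
        return StatResult(
            test_name="mixed_anova_F",
            statistic=float(row["F"]),
            df=(df1, df2),
            p_value=p,
            effect_size=float(row["np2"]),
            effect_size_name="partial_eta_sq",
            assumptions_log=log,
            extra={"source": source},
        )

    results = {
        "within": row_result(within, corrected=True),
        "between": row_result(between, corrected=False),
        "interaction": row_result("Interaction", corrected=True),
    }

    tukey_between = pairwise_tukeyhsd(data[dv], data[between])
    results["posthoc_between"] = StatResult(
        test_name="tukey_hsd",
        statistic=float(tukey_between.meandiffs[0]),
        df=None,
        p_value=float(tukey_between.pvalues[0]),
        ci_low=float(tukey_between.confint[0][0]),
        ci_high=float(tukey_between.confint[0][1]),
        assumptions_log=log,
        extra={"contrast": list(map(str, tukey_between.groupsunique))},
    )
    tukey_within = pairwise_tukeyhsd(data[dv], data[within].astype(str))
    pairs = [
        f"{a}-{b}"
        for i, a in enumerate(tukey_within.groupsunique)
        for b in tukey_within.groupsunique[i + 1:]
    ]
    results["posthoc_within"] = StatResult(
        test_name="tukey_hsd",
        statistic=math.nan,
        df=None,
        p_value=math.nan,
        assumptions_log=log,
        extra={
            "pairs": pairs,
            "mean_diffs": [float(x) for x in tukey_within.meandiffs],
            "p_values": [float(x) for x in tukey_within.pvalues],
        },
    )
    return results


# ---------------------------------------------------------------------------
# subgroup analyses
# ---------------------------------------------------------------------------

CONSUMPTION_BINS = (15.0, 30.0)  # left-closed: [0,15), [15,30), [30,inf)


def consumption_tertile(hours_per_week: float) -> str:
    if hours_per_week < CONSUMPTION_BINS[0]:
        return "Low"
    if hours_per_week < CONSUMPTION_BINS[1]:
        return "Average"
    return "High"


def subgroup_analyses(
    table: pd.DataFrame,
    score_cols: tuple[str, ...] = ("mle",),
) -> dict[str, StatResult]:
    """Confounder checks: age correlations, consumption-tertile and
    content-group one-way ANOVAs on MLE, gender and group x gender tests."""
    out: dict[str, StatResult] = {}
    for col in score_cols:
        sub = table.dropna(subset=["age", col])
        r, p = stats.pearsonr(sub["age"], sub[col])
        out[f"age_corr_{col}"] = StatResult(
            test_name="pearson_r",
            statistic=float(r),
            df=len(sub) - 2,
            p_value=float(p),
            effect_size=float(r),
            effect_size_name="r",
            extra={"n": len(sub)},
        )

    table = table.copy()
    table["consumption_bin"] = table["consumption_h_week"].map(consumption_tertile)
    skipped: list[str] = []

    def try_oneway(key: str, frame: pd.DataFrame, factor: str):
        try:
            out[key] = _oneway(frame, factor, "mle")
        except MissingDataError as exc:
            skipped.append(f"{key}: {exc}")
            warnings.warn(str(exc), stacklevel=2)

    try_oneway("consumption_anova_mle", table, "consumption_bin")
    tv = table[(table["group"] == "TV") & (table["content_group"] != "")]
    try_oneway("content_anova_mle", tv, "content_group")

    if table["gender"].nunique() == 2:
        g1, g2 = sorted(table["gender"].unique())
        out["gender_mle"] = compare_groups(
            table, "mle", group_col="gender", order=(g1, g2)
        )
    combo = table.assign(gg=table["group"] + "/" + table["gender"])
    try_oneway("group_gender_anova_mle", combo, "gg")
    if skipped:
        out["_skipped"] = StatResult(
            test_name="skipped_subgroups", statistic=math.nan, df=None,
            p_value=math.nan, extra={"skipped": skipped},
        )
    return out


def _oneway(table: pd.DataFrame, factor: str, dv: str) -> StatResult:
    groups = [
        g[dv].dropna().to_numpy(float)
        for _, g in table.groupby(factor)
        if len(g[dv].dropna()) >= 2
    ]
    if len(groups) < 2:
        raise MissingDataError(f"one-way ANOVA on {factor}: fewer than 2 usable groups")
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return StatResult(
        test_name="oneway_anova",
        statistic=float(f),
        df=(k - 1, n - k),
        p_value=float(p),
        extra={"factor": factor, "n_groups": k, "n": n},
    )
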