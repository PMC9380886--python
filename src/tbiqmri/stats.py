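"""Group statistics: two-sample t, one-way ANOVA + Tukey HSD, Pearson r.

Mirrors a conventional small-animal imaging analysis plan: exploratory
sex comparisons with uncorrected independent-sample t-tests, severity
comparisons with one-way ANOVA followed by Tukey's post-hoc test, and
Pearson correlation for brain-behavior relationships. No multiplicity
correction is applied beyond Tukey's adjustment.

The t-test is the pooled-variance (Student) form by default, with Welch
available via a flag. Degenerate zero-variance inputs follow explicit
conventions instead of propagating NaNs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.values = self.values[np.isfinite(self.values)]

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    estimate: float | None = None
    pair: tuple[str, str] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    x_metric: str = ""
    y_metric: str = ""
    roi: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")


def _as_sample(x, label="") -> GroupSample:
    return x if isinstance(x, GroupSample) else GroupSample(label, np.asarray(x, float))


def ttest_independent(a, b, welch: bool = False) -> TestResult:
    """Two-sided independent-sample t-test (pooled variance by default).

    Zero pooled variance: equal means -> t=0, p=1; unequal means -> p=0
    with an infinite statistic, flagged 'zero_variance'.
    """
    a, b = _as_sample(a, "a"), _as_sample(b, "b")
    if a.n < 2 or b.n < 2:
        raise ValueError("both samples need n >= 2")
    df = a.n + b.n - 2
    va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        ma, mb = a.values.mean(), b.values.mean()
        if ma == mb:
            return TestResult(0.0, df, 1.0, 0.0, flags=["zero_variance"])
        return TestResult(np.inf if ma > mb else -np.inf, df, 0.0, ma - mb,
                          flags=["zero_variance"])
    res = sps.ttest_ind(a.values, b.values, equal_var=not welch)
    df_out = float(res.df) if welch else df
    return TestResult(float(res.statistic), df_out, float(res.pvalue),
                      float(a.values.mean() - b.values.mean()))


def anova_oneway(groups: list) -> TestResult:
    """One-way fixed-effects ANOVA; F = MS_between / MS_within."""
    gs = [_as_sample(g, str(i)) for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(g.n < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    k = len(gs)
    ns = np.array([g.n for g in gs])
    N = int(ns.sum())
    means = np.array([g.values.mean() for g in gs])
    grand = np.concatenate([g.values for g in gs]).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g.values - m) ** 2).sum() for g, m in zip(gs, means)))
    df = (k - 1, N - k)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(0.0, df, 1.0, flags=["degenerate"])
        return TestResult(np.inf, df, 0.0, flags=["degenerate"])
    F = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(F, *df))
    return TestResult(float(F), df, p)


def tukey_hsd(groups: list, labels: list[str] | None = None) -> list[TestResult]:
    """All-pairs Tukey HSD (Tukey-Kramer for unequal n).

    Adjusted p-values come from the studentized-range distribution. The
    returned per-pair estimates are mean differences (first minus second).
    """
    gs = [_as_sample(g, str(i)) for i, g in enumerate(groups)]
    if labels is None:
        labels = [g.label or str(i) for i, g in enumerate(gs)]
    if any(g.n < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    k = len(gs)
    N = sum(g.n for g in gs)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in gs)
    out = []
    if ss_within == 0.0:
        for i, j in itertools.combinations(range(k), 2):
            d = gs[i].values.mean() - gs[j].values.mean()
            p = 1.0 if d == 0 else 0.0
            out.append(TestResult(0.0 if d == 0 else np.inf, (k, N - k), p, d,
                                  pair=(labels[i], labels[j]), flags=["degenerate"]))
        return out
    res = sps.tukey_hsd(*[g.values for g in gs])
    for i, j in itertools.combinations(range(k), 2):
        d = float(gs[i].values.mean() - gs[j].values.mean())
        out.append(TestResult(float(res.statistic[i, j]), (k, N - k),
                              float(np.clip(res.pvalue[i, j], 0.0, 1.0)), d,
                              pair=(labels[i], labels[j])))
    return out


def pearson(x, y, x_metric: str = "", y_metric: str = "",
            roi: str = "", timepoint: str = "") -> CorrelationResult:
    """Pearson correlation with two-sided p from t = r sqrt((n-2)/(1-r^2));
    pairs with a missing member are dropped listwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation needs n >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), int(x.size), float(p),
                             x_metric, y_metric, roi, timepoint)


# ---------------------------------------------------------------------------
# study-design driver
# ---------------------------------------------------------------------------

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return ""


@dataclass
class StudyDesign:
    """The two-stage analysis plan plus pre-registered correlation pairs.

    ``correlation_pairs``: (metric, roi, timepoint, outcome) tuples —
    e.g. ('aptw', 'core', '1d', 'mnss').
    """

    metrics: tuple[str, ...] = ("t1", "t2", "adc", "cbf", "aptw", "mtr")
    rois: tuple[str, ...] = ("core", "ipsi_cortex", "contra_cortex",
                             "ipsi_hippocampus", "contra_hippocampus",
                             "ipsi_thalamus", "contra_thalamus")
    timepoints: tuple[str, ...] = ("1h", "1d", "3d")
    sex_metric: str = "aptw"
    group_order: tuple[str, ...] = ("sham", "mild", "moderate", "severe")
    reference_group: str = "sham"
    correlation_pairs: tuple[tuple[str, str, str, str], ...] = (
        ("aptw", "core", "1d", "mnss"),
        ("aptw", "core", "1d", "spr"),
        ("aptw", "core", "1d", "barnes_escape_s"),
        ("aptw", "ipsi_hippocampus", "1d", "fst_immobile_s"),
        ("aptw", "ipsi_cortex", "3d", "iba1_ic"),
        ("aptw", "ipsi_cortex", "3d", "mnss"),
        ("aptw", "ipsi_cortex", "3d", "spr"),
        ("aptw", "ipsi_thalamus", "3d", "iba1_it"),
    )


def _metric_frame(table: pd.DataFrame, metric: str, roi: str, tp: str) -> pd.DataFrame:
    sel = ((table["metric_name"] == metric) & (table["roi_name"] == roi)
           & (table["timepoint"] == tp))
    return table.loc[sel]


def run_study_design(table: pd.DataFrame, design: StudyDesign | None = None) -> dict:
    """Run the full statistical battery on a long-format cohort table.

    Returns dict of DataFrames: 'sex_differences' (uncorrected t-tests of
    the sex_metric per CCI group/ROI/timepoint), 'group_comparisons'
    (ANOVA + all-pairs Tukey with versus-reference rows starred), and
    'correlations' (Pearson r for the pre-registered pairs, listwise
    deletion of missing outcomes).
    """
    design = design or StudyDesign()
    for col in ("metric_name", "roi_name", "timepoint", "mean", "group", "subject_id"):
        if col not in table.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    for m in design.metrics:
        if not (table["metric_name"] == m).any():
            raise ValueError(f"metric {m!r} absent from the cohort table")
    for r in design.rois:
        if not (table["roi_name"] == r).any():
            raise ValueError(f"ROI {r!r} absent from the cohort table")

    sex_rows = []
    if "sex" in table.columns:
        for g in design.group_order:
            if g == design.reference_group:
                continue
            for tp in design.timepoints:
                for roi in design.rois:
                    sub = _metric_frame(table, design.sex_metric, roi, tp)
                    sub = sub[sub["group"] == g]
                    males = sub.loc[sub["sex"] == "M", "mean"].values
                    females = sub.loc[sub["sex"] == "F", "mean"].values
                    if males.size < 2 or females.size < 2:
                        continue
                    res = ttest_independent(males, females)
                    sex_rows.append({"group": g, "timepoint": tp, "roi_name": roi,
                                     "metric_name": design.sex_metric,
                                     "t": res.statistic, "df": res.df,
                                     "p_value": res.p_value,
                                     "mean_diff_m_minus_f": res.estimate})
    sex_df = pd.DataFrame(sex_rows)

    grp_rows = []
    for metric in design.metrics:
        for tp in design.timepoints:
            for roi in design.rois:
                sub = _metric_frame(table, metric, roi, tp)
                samples, labels = [], []
                for g in design.group_order:
                    v = sub.loc[sub["group"] == g, "mean"].values
                    if v.size >= 2:
                        samples.append(v)
                        labels.append(g)
                if len(samples) < 2:
                    continue
                an = anova_oneway(samples)
                pairs = tukey_hsd(samples, labels)
                for pr in pairs:
                    vs_ref = design.reference_group in pr.pair
                    grp_rows.append({
                        "metric_name": metric, "timepoint": tp, "roi_name": roi,
                        "anova_F": an.statistic, "anova_df1": an.df[0],
                        "anova_df2": an.df[1], "anova_p": an.p_value,
                        "pair": f"{pr.pair[0]} vs {pr.pair[1]}",
                        "mean_diff": pr.estimate, "tukey_p": pr.p_value,
                        "vs_reference": vs_ref,
                        "stars": significance_stars(pr.p_value) if vs_ref else "",
                    })
    grp_df = pd.DataFrame(grp_rows)

    corr_rows = []
    outcome_cols = [c for c in table.columns
                    if c not in {"subject_id", "sex", "group", "timepoint", "roi_name",
                                 "metric_name", "mean", "sd", "n_valid_voxels",
                                 "early_sacrifice"}]
    for metric, roi, tp, outcome in design.correlation_pairs:
        if outcome not in outcome_cols:
            raise ValueError(f"outcome column {outcome!r} missing from the cohort table")
        sub = _metric_frame(table, metric, roi, tp)
        try:
            res = pearson(sub["mean"].values, sub[outcome].values,
                          x_metric=metric, y_metric=outcome, roi=roi, timepoint=tp)
            row = {"r": res.r, "n": res.n, "p_value": res.p_value,
                   "stars": significance_stars(res.p_value), "note": ""}
        except ValueError as exc:
            # a pre-registered pair the data cannot answer (too few complete
            # pairs / no variance) is reported, not fatal
            n_complete = int((sub["mean"].notna() & sub[outcome].notna()).sum())
            row = {"r": np.nan, "n": n_complete, "p_value": np.nan,
                   "stars": "", "note": str(exc)}
        corr_rows.append({"metric_name": metric, "roi_name": roi, "timepoint": tp,
                          "outcome": outcome, **row})
    corr_df = pd.DataFrame(corr_rows)

    return {"sex_differences": sex_df, "group_comparisons": grp_df,
            "correlations": corr_df}


__all__ = [
    "GroupSample", "TestResult", "CorrelationResult", "StudyDesign",
    "ttest_independent", "anova_oneway", "tukey_hsd", "pearson",
    "significance_stars", "run_study_design", "STAR_LEVELS",
]
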