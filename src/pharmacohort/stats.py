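"""Between-group comparisons: t tests, Cohen d, ANCOVA screen, demographics.

Per-patient difference scores (after-window outcome minus before-window
outcome) are compared between study groups with independent-samples
Student t tests (pooled variance, df = n1 + n2 - 2, matching the reported
degrees of freedom), oriented as control minus intervention. Cohen d uses
the pooled SD of the analyzed scores. Covariates (age, gender) are
screened by analysis of covariance on the difference scores; a significant
covariate triggers stratified re-analysis. Demographic contrasts use
Pearson chi-square (2x2 on male/female, the unknown category shown
descriptively only) and pooled t tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """The inputs carry no variance to test."""


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance independent-samples t test, control minus intervention."""

    mean_diff_sara: float
    mean_diff_control: float
    t_statistic: float
    df: int
    p_value: float
    ci95: tuple
    cohen_d: float
    n_sara: int
    n_control: int

    @property
    def contrast(self) -> float:
        """Between-group mean difference (control - intervention)."""
        return self.mean_diff_control - self.mean_diff_sara


def diff_score_ttest(diffs_sara, diffs_control) -> TTestResult:
    """Compare per-patient difference scores between the study groups.

    Student (pooled-variance) two-sided t test on control minus
    intervention, with the 95% CI for the between-group mean difference and
    Cohen d = contrast / pooled SD.
    """
    a = np.asarray(diffs_control, dtype=float)
    b = np.asarray(diffs_sara, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("each group needs >= 2 finite values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DegenerateDataError("non-finite values in input")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if s2 <= 0:
        raise DegenerateDataError("zero pooled variance")
    pooled_sd = np.sqrt(s2)
    contrast = a.mean() - b.mean()
    se = pooled_sd * np.sqrt(1.0 / n1 + 1.0 / n2)
    t = contrast / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    return TTestResult(
        mean_diff_sara=float(b.mean()), mean_diff_control=float(a.mean()),
        t_statistic=float(t), df=int(df), p_value=float(p),
        ci95=(float(contrast - tcrit * se), float(contrast + tcrit * se)),
        cohen_d=float(contrast / pooled_sd), n_sara=n2, n_control=n1)


def new_user_ttest(pdc_after_sara, pdc_after_control) -> TTestResult:
    """Single-period comparison of new users' post-index adherence."""
    return diff_score_ttest(pdc_after_sara, pdc_after_control)


@dataclass
class AncovaResult:
    """Covariate screen on difference scores."""

    covariate_p_values: dict
    significant_covariates: list
    adjusted_group_effect: float
    adjusted_group_p_value: float
    n: int
    stratified: dict = field(default_factory=dict)


def ancova_screen(outcome_diffs, group, age, gender,
                  alpha: float = ALPHA) -> AncovaResult:
    """Linear model of the difference score on group + age + gender.

    Age and gender p-values flag influential covariates; when gender is
    significant the group contrast is re-run within each gender stratum
    (unknown gender excluded from the stratified runs).
    """
    frame = pd.DataFrame({
        "diff": np.asarray(outcome_diffs, dtype=float),
        "group": np.asarray(group),
        "age": np.asarray(age, dtype=float),
        "gender": np.asarray(gender),
    }).dropna()
    frame = frame.loc[frame["gender"].isin(["male", "female"])]
    if frame["age"].nunique() <= 1:
        raise DegenerateDataError("age is constant")
    if frame["gender"].nunique() <= 1:
        raise DegenerateDataError("gender is constant")
    model = smf.ols(
        "diff ~ C(group, Treatment('control')) + age + C(gender)",
        data=frame).fit()
    cov_p = {
        "age": float(model.pvalues["age"]),
        "gender": float(model.pvalues["C(gender)[T.male]"]),
    }
    significant = [k for k, v in cov_p.items() if v <= alpha]
    group_term = "C(group, Treatment('control'))[T.sara]"
    result = AncovaResult(
        covariate_p_values=cov_p,
        significant_covariates=significant,
        adjusted_group_effect=float(model.params[group_term]),
        adjusted_group_p_value=float(model.pvalues[group_term]),
        n=int(model.nobs))
    if "gender" in significant:
        for level in ("male", "female"):
            sub = frame.loc[frame["gender"] == level]
            sara = sub.loc[sub["group"] == "sara", "diff"]
            ctrl = sub.loc[sub["group"] == "control", "diff"]
            if len(sara) >= 2 and len(ctrl) >= 2:
                result.stratified[level] = diff_score_ttest(sara, ctrl)
    return result


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on [[a, b], [c, d]]."""
    stat, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(stat), float(p)


def demographics_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographic summary with group-contrast p-values.

    ``frame`` needs columns group, gender and age_at_first_dispensing.
    Gender is contrasted with a 2x2 Pearson chi-square over male/female
    (the unknown row is reported descriptively), age with a pooled t test.
    """
    rows = []
    groups = {"sara": frame.loc[frame["group"] == "sara"],
              "control": frame.loc[frame["group"] == "control"]}
    n_total = len(frame)
    for g, sub in groups.items():
        rows.append({"characteristic": "n", "group": g, "value": len(sub),
                     "pct": round(100.0 * len(sub) / n_total, 2)})

    counts = {g: sub["gender"].value_counts() for g, sub in groups.items()}
    chi2_p = np.nan
    a = int(counts["sara"].get("male", 0))
    b = int(counts["sara"].get("female", 0))
    c = int(counts["control"].get("male", 0))
    d = int(counts["control"].get("female", 0))
    if min(a + b, c + d) > 0:
        _, chi2_p = chi2_2x2(a, b, c, d)
    for g, sub in groups.items():
        n = len(sub)
        for level in ("male", "female", "unknown"):
            k = int(counts[g].get(level, 0))
            rows.append({
                "characteristic": f"gender_{level}", "group": g, "value": k,
                "pct": round(100.0 * k / n, 2) if n else np.nan,
                "p_value": chi2_p if level == "male" else np.nan})

    age_p = np.nan
    if len(groups["sara"]) >= 2 and len(groups["control"]) >= 2:
        try:
            t = diff_score_ttest(
                groups["sara"]["age_at_first_dispensing"],
                groups["control"]["age_at_first_dispensing"])
            age_p = t.p_value
        except DegenerateDataError:
            pass
    for g, sub in groups.items():
        rows.append({
            "characteristic": "age_mean", "group": g,
            "value": round(float(sub["age_at_first_dispensing"].mean()), 1),
            "pct": np.nan, "p_value": age_p})
        rows.append({
            "characteristic": "age_sd", "group": g,
            "value": round(float(sub["age_at_first_dispensing"].std(ddof=1)), 1),
            "pct": np.nan})
    return pd.DataFrame(rows)


def group_share_percent(n_group: int, n_total: int) -> float:
    """Percentage share of a group, reported to two decimals."""
    return round(100.0 * n_group / n_total, 2)
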