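"""Statistical layer: cohort exclusions, Bland-Altman method agreement,
case-control comparisons, and sex / OI-type subgroup analyses.

Conventions, fixed for reproducibility:

* Sample SD uses the n-1 denominator throughout; all p-values two-sided;
  no multiple-testing correction is applied.
* Bland-Altman differences are oriented fixed - GMM, so methods that read
  higher under the adaptive model yield negative mean differences; 95%
  limits of agreement are mean +/- 1.96 SD of the differences.
* The two-sample t test is variance-gated by default: Levene's test
  (mean-centered) at alpha = 0.05 selects the pooled-variance or the Welch
  (Satterthwaite) statistic, mirroring common statistical-package behavior.
  Both variants are exposed directly.
* Chi-square on 2x2 tables is Pearson's statistic without continuity
  correction, df = 1.
* Table formatting: measurement summaries to 1 decimal, agreement
  statistics to 2 decimals, p to 2 decimals with "< 0.01" printed below
  0.005.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ct_io import SubjectRecord
from .errors import InvalidPairsError, TrunkCompError

GATE_ALPHA = 0.05
LOA_Z = 1.96

#: (level, metric, display name) for the four measurement variables
MEASUREMENT_VARIABLES = (
    ("midT4", "area_cm2", "T4 muscle size (cm2)"),
    ("midT4", "density_hu", "T4 muscle density (HU)"),
    ("midT10", "area_cm2", "T10 muscle size (cm2)"),
    ("midT10", "density_hu", "T10 muscle density (HU)"),
)


# ---------------------------------------------------------------------------
# Cohort filter


@dataclass
class CohortFilterReport:
    n_screened: int
    n_excluded_by_reason: dict[str, int]
    n_excluded: int  # distinct subjects excluded
    n_enrolled: int
    n_multi_reason: int = 0  # subjects carrying more than one flag


def apply_exclusions(subjects: Sequence[SubjectRecord]
                     ) -> tuple[list[SubjectRecord], CohortFilterReport]:
    """Drop subjects carrying any exclusion flag and account for them.

    A subject with several flags is excluded once in the enrollment
    arithmetic but listed under every reason; ``n_multi_reason`` makes the
    double counting explicit.
    """
    enrolled = [s for s in subjects if not s.exclusion_flags]
    excluded = [s for s in subjects if s.exclusion_flags]
    by_reason: dict[str, int] = {}
    for s in excluded:
        for reason in sorted(s.exclusion_flags):
            by_reason[reason] = by_reason.get(reason, 0) + 1
    report = CohortFilterReport(
        n_screened=len(subjects), n_excluded_by_reason=by_reason,
        n_excluded=len(excluded), n_enrolled=len(enrolled),
        n_multi_reason=sum(1 for s in excluded if len(s.exclusion_flags) > 1))
    return enrolled, report


# ---------------------------------------------------------------------------
# Method agreement


@dataclass
class BlandAltmanResult:
    """Agreement between two measurement methods on paired data."""

    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    n_pairs: int


def bland_altman(method_a: Sequence[float], method_b: Sequence[float]
                 ) -> BlandAltmanResult:
    """Mean paired difference (A - B) and 95% limits of agreement.

    The limits mean +/- 1.96 SD bracket ~95% of between-method differences
    when those differences are approximately normal, which is the criterion
    for using the methods interchangeably.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidPairsError(f"paired lists must match: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise InvalidPairsError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean_difference=mean, sd_difference=sd,
                             loa_lower=mean - LOA_Z * sd,
                             loa_upper=mean + LOA_Z * sd, n_pairs=a.size)


# ---------------------------------------------------------------------------
# Two-sample comparisons


@dataclass
class GroupComparison:
    variable: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    variance_gate: str  # 'pooled' | 'welch'
    gate_p: Optional[float]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def levene_center_mean(*groups: Sequence[float]) -> float:
    """Levene's homogeneity-of-variance test, mean-centered: one-way ANOVA
    on absolute deviations from each group's mean.  Degenerate (all-equal)
    input returns p = 1 so the downstream gate defaults to pooled."""
    if len(groups) < 2:
        raise TrunkCompError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise TrunkCompError("every group needs n >= 2")
    devs = [np.abs(a - a.mean()) for a in arrays]
    if all(np.ptp(d) == 0 for d in devs) and len({d[0] for d in devs}) == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = sps.levene(*arrays, center="mean")
    return 1.0 if np.isnan(p) else float(p)


def _pooled_welch(mean_a, sd_a, n_a, mean_b, sd_b, n_b, pooled: bool):
    t, p = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                    equal_var=pooled)
    if pooled:
        df = n_a + n_b - 2
    else:
        va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
        if va + vb == 0:
            df = n_a + n_b - 2
        else:
            df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    if np.isnan(t):  # zero variance in both groups
        t = 0.0 if mean_a == mean_b else np.inf * np.sign(mean_a - mean_b)
        p = 1.0 if mean_a == mean_b else 0.0
    return float(t), float(df), float(p)


def t_test_from_samples(group_a: Sequence[float], group_b: Sequence[float],
                        gate_alpha: float = GATE_ALPHA,
                        variant: str = "auto",
                        variable: str = "") -> GroupComparison:
    """Two-sample t test with a Levene variance gate.

    ``variant='auto'`` (default) uses the pooled-variance statistic unless
    Levene's test rejects variance homogeneity at ``gate_alpha``, in which
    case the Welch statistic with Satterthwaite df is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise TrunkCompError("each group needs n >= 2")
    if variant == "auto":
        gate_p = levene_center_mean(a, b)
        gate = "welch" if gate_p < gate_alpha else "pooled"
    elif variant in ("pooled", "welch"):
        gate_p, gate = None, variant
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t, df, p = _pooled_welch(a.mean(), a.std(ddof=1), a.size,
                             b.mean(), b.std(ddof=1), b.size,
                             pooled=(gate == "pooled"))
    return GroupComparison(variable=variable,
                           mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                           n_a=a.size, mean_b=float(b.mean()),
                           sd_b=float(b.std(ddof=1)), n_b=b.size,
                           variance_gate=gate, gate_p=gate_p,
                           t_statistic=t, degrees_of_freedom=df, p_value=p)


def t_test_from_summary(mean_a: float, sd_a: float, n_a: int,
                        mean_b: float, sd_b: float, n_b: int,
                        variant: str = "auto",
                        gate_alpha: float = GATE_ALPHA,
                        variable: str = "") -> GroupComparison:
    """t test from printed (mean, SD, n) summaries.

    With ``variant='auto'`` the variance gate is the two-sided F ratio test
    on sd_a^2/sd_b^2 at ``gate_alpha`` — the summary-statistic surrogate for
    Levene's test, which needs raw data.
    """
    if n_a < 2 or n_b < 2:
        raise TrunkCompError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise TrunkCompError("sd must be >= 0")
    gate_p = None
    if variant == "auto":
        if sd_a == 0 and sd_b == 0:
            gate_p, gate = 1.0, "pooled"
        else:
            big, small = max(sd_a, sd_b), min(sd_a, sd_b)
            dfn = (n_a - 1) if sd_a >= sd_b else (n_b - 1)
            dfd = (n_b - 1) if sd_a >= sd_b else (n_a - 1)
            F = np.inf if small == 0 else (big / small) ** 2
            gate_p = float(min(1.0, 2.0 * sps.f.sf(F, dfn, dfd)))
            gate = "welch" if gate_p < gate_alpha else "pooled"
    elif variant in ("pooled", "welch"):
        gate = variant
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t, df, p = _pooled_welch(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                             pooled=(gate == "pooled"))
    return GroupComparison(variable=variable, mean_a=mean_a, sd_a=sd_a,
                           n_a=n_a, mean_b=mean_b, sd_b=sd_b, n_b=n_b,
                           variance_gate=gate, gate_p=gate_p, t_statistic=t,
                           degrees_of_freedom=df, p_value=p)


def chi_square_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise TrunkCompError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise TrunkCompError("all row and column margins must be positive")
    (a, b), (c, d) = t
    n = t.sum()
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = float(n * (a * d - b * c) ** 2 / denom)
    return chi2, float(sps.chi2.sf(chi2, df=1))


def one_way_anova(*groups: Sequence[float]) -> tuple[float, tuple[int, int], float]:
    """One-way between/within ANOVA: (F, (df_between, df_within), p).

    With two groups F equals the square of the pooled t statistic.  A fully
    constant dataset returns F = 0, p = 1 rather than 0/0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise TrunkCompError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise TrunkCompError("every group must be non-empty")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if n_total <= k:
        raise TrunkCompError("total n must exceed the number of groups")
    df = (k - 1, n_total - k)
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        return 0.0, df, 1.0
    with np.errstate(invalid="ignore"):
        F, p = sps.f_oneway(*arrays)
    if np.isnan(F):  # zero within-group variance, distinct means
        return float("inf"), df, 0.0
    return float(F), df, float(p)


# ---------------------------------------------------------------------------
# Table builders


def format_p(p: float) -> str:
    return "< 0.01" if p < 0.005 else f"{p:.2f}"


def format_mean_sd(mean: float, sd: float, decimals: int = 1) -> str:
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def _pivot_variable(measurements: pd.DataFrame, level: str, metric: str,
                    method: str) -> pd.Series:
    sel = measurements[(measurements["level"] == level)
                       & (measurements["method"] == method)]
    return sel.set_index("subject_id")[metric]


def build_method_agreement_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Bland-Altman summary per measurement variable (fixed - GMM)."""
    rows = []
    for level, metric, name in MEASUREMENT_VARIABLES:
        fixed = _pivot_variable(measurements, level, metric, "fixed")
        gmm = _pivot_variable(measurements, level, metric, "gmm")
        common = fixed.index.intersection(gmm.index)
        pair = pd.DataFrame({"fixed": fixed[common], "gmm": gmm[common]}).dropna()
        if len(pair) < 2:  # too few pairs: flagged gap, not an error
            rows.append({"variable": name, "n_pairs": len(pair),
                         "mean_difference": np.nan, "sd_difference": np.nan,
                         "loa_lower": np.nan, "loa_upper": np.nan,
                         "mean_difference_fmt": "",
                         "loa_fmt": "insufficient pairs"})
            continue
        ba = bland_altman(pair["fixed"].to_numpy(), pair["gmm"].to_numpy())
        rows.append({
            "variable": name, "n_pairs": ba.n_pairs,
            "mean_difference": ba.mean_difference,
            "sd_difference": ba.sd_difference,
            "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
            "mean_difference_fmt": f"{ba.mean_difference:.2f}",
            "loa_fmt": f"{ba.loa_lower:.2f} to {ba.loa_upper:.2f}"})
    return pd.DataFrame(rows)


def bland_altman_plot_data(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-subject (mean, difference) pairs with limit lines, one block per
    variable — the data behind a Bland-Altman plot."""
    rows = []
    for level, metric, name in MEASUREMENT_VARIABLES:
        fixed = _pivot_variable(measurements, level, metric, "fixed")
        gmm = _pivot_variable(measurements, level, metric, "gmm")
        common = fixed.index.intersection(gmm.index)
        pair = pd.DataFrame({"fixed": fixed[common], "gmm": gmm[common]}).dropna()
        if len(pair) < 2:
            continue
        ba = bland_altman(pair["fixed"].to_numpy(), pair["gmm"].to_numpy())
        for sid, row in pair.iterrows():
            rows.append({"variable": name, "subject_id": sid,
                         "pair_mean": (row["fixed"] + row["gmm"]) / 2.0,
                         "difference": row["fixed"] - row["gmm"],
                         "mean_difference": ba.mean_difference,
                         "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper})
    return pd.DataFrame(rows)


_DEMOGRAPHICS = (("age", "Age"), ("weight", "Weight (kg)"),
                 ("height", "Height (cm)"), ("bmi", "BMI (kg/m2)"))


def build_group_comparison_table(measurements: pd.DataFrame,
                                 subjects: Sequence[SubjectRecord],
                                 variant: str = "auto") -> pd.DataFrame:
    """Case-control table: demographics (t tests + sex chi-square) followed
    by the eight measurement comparisons (2 methods x 2 levels x 2 metrics)."""
    subj_df = pd.DataFrame([{
        "subject_id": s.subject_id, "group": s.group, "sex": s.sex,
        "age": s.age, "weight": s.weight, "height": s.height, "bmi": s.bmi}
        for s in subjects])
    oi = subj_df[subj_df["group"] == "OI"]
    ctrl = subj_df[subj_df["group"] == "control"]
    if oi.empty or ctrl.empty:
        missing = "OI" if oi.empty else "control"
        df = pd.DataFrame({"variable": [f"[{missing} group absent]"]})
        df["comparison"] = "absent"
        return df
    rows = []

    males = [int((g["sex"] == "male").sum()) for g in (oi, ctrl)]
    females = [int((g["sex"] == "female").sum()) for g in (oi, ctrl)]
    if min(males + females) > 0:
        chi2, p_sex = chi_square_2x2([[males[0], females[0]],
                                      [males[1], females[1]]])
        rows.append({"variable": "Gender (male/female)",
                     "oi_summary": f"{males[0]}/{females[0]}",
                     "control_summary": f"{males[1]}/{females[1]}",
                     "test": "chi-square", "statistic": chi2,
                     "p_value": p_sex, "p_fmt": format_p(p_sex)})

    for col, name in _DEMOGRAPHICS:
        cmp_ = t_test_from_samples(oi[col], ctrl[col], variant=variant,
                                   variable=name)
        rows.append({"variable": name,
                     "oi_summary": format_mean_sd(cmp_.mean_a, cmp_.sd_a),
                     "control_summary": format_mean_sd(cmp_.mean_b, cmp_.sd_b),
                     "test": f"t ({cmp_.variance_gate})",
                     "statistic": cmp_.t_statistic,
                     "p_value": cmp_.p_value, "p_fmt": format_p(cmp_.p_value)})

    oi_ids = set(oi["subject_id"])
    ctrl_ids = set(ctrl["subject_id"])
    for method in ("fixed", "gmm"):
        for level, metric, name in MEASUREMENT_VARIABLES:
            series = _pivot_variable(measurements, level, metric, method).dropna()
            a = series[series.index.isin(oi_ids)]
            b = series[series.index.isin(ctrl_ids)]
            cmp_ = t_test_from_samples(a, b, variant=variant, variable=name)
            rows.append({"variable": f"{name} [{method}]",
                         "oi_summary": format_mean_sd(cmp_.mean_a, cmp_.sd_a),
                         "control_summary": format_mean_sd(cmp_.mean_b, cmp_.sd_b),
                         "test": f"t ({cmp_.variance_gate})",
                         "statistic": cmp_.t_statistic,
                         "p_value": cmp_.p_value,
                         "p_fmt": format_p(cmp_.p_value)})
    return pd.DataFrame(rows)


def build_subgroup_table(measurements: pd.DataFrame,
                         subjects: Sequence[SubjectRecord],
                         method: str, variant: str = "auto") -> pd.DataFrame:
    """Sex and OI-type subgroup analyses for one segmentation method:
    male-vs-female t tests within cases and within controls, and a one-way
    ANOVA across OI types, per measurement variable."""
    meta = {s.subject_id: s for s in subjects}
    rows = []
    for level, metric, name in MEASUREMENT_VARIABLES:
        series = _pivot_variable(measurements, level, metric, method).dropna()

        def vals(pred):
            return np.array([v for sid, v in series.items()
                             if sid in meta and pred(meta[sid])])

        for group in ("OI", "control"):
            m = vals(lambda s, g=group: s.group == g and s.sex == "male")
            f = vals(lambda s, g=group: s.group == g and s.sex == "female")
            if m.size >= 2 and f.size >= 2:
                cmp_ = t_test_from_samples(m, f, variant=variant, variable=name)
                p, test = cmp_.p_value, f"t ({cmp_.variance_gate})"
            else:
                p, test = np.nan, "insufficient n"
            rows.append({"section": f"{group}_sex", "variable": name,
                         "male_summary": format_mean_sd(m.mean(), m.std(ddof=1))
                         if m.size >= 2 else "", "n_male": m.size,
                         "female_summary": format_mean_sd(f.mean(), f.std(ddof=1))
                         if f.size >= 2 else "", "n_female": f.size,
                         "test": test, "p_value": p,
                         "p_fmt": format_p(p) if np.isfinite(p) else ""})

        type_samples = {t: vals(lambda s, t=t: s.group == "OI" and s.oi_type == t)
                        for t in ("I", "III", "IV")}
        type_samples = {t: v for t, v in type_samples.items() if v.size > 0}
        if len(type_samples) >= 2 and sum(v.size for v in type_samples.values()) \
                > len(type_samples):
            F, _, p = one_way_anova(*type_samples.values())
            test = "ANOVA"
        else:
            F, p, test = np.nan, np.nan, "insufficient groups"
        rows.append({"section": "OI_type", "variable": name,
                     "male_summary": "", "n_male": 0,
                     "female_summary": "", "n_female": 0,
                     "test": test, "p_value": p,
                     "p_fmt": format_p(p) if np.isfinite(p) else ""})
    return pd.DataFrame(rows)


def build_tables(measurements: pd.DataFrame,
                 subjects: Sequence[SubjectRecord],
                 variant: str = "auto") -> dict[str, pd.DataFrame]:
    """All analysis tables from one measurement table and subject roster:
    method agreement, case-control comparison, and per-method subgroups."""
    return {
        "method_agreement": build_method_agreement_table(measurements),
        "group_comparison": build_group_comparison_table(
            measurements, subjects, variant=variant),
        "subgroups_fixed": build_subgroup_table(
            measurements, subjects, "fixed", variant=variant),
        "subgroups_gmm": build_subgroup_table(
            measurements, subjects, "gmm", variant=variant),
        "bland_altman_points": bland_altman_plot_data(measurements),
    }
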