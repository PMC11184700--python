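"""Statistical layer: exclusions, Bland-Altman, gated t tests, chi-square,
ANOVA, and the table builders on an exactly moment-matched cohort."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trunkcomp as tc
from trunkcomp import reference
from trunkcomp.errors import InvalidPairsError, TrunkCompError
from trunkcomp.stats import format_p


# ---------------------------------------------------------------------------
# Cohort filter


def _subject(i, group="OI", flags=()):
    oi_type = "I" if group == "OI" else "none"
    return tc.SubjectRecord(f"s{i}", group, "male", 9, 30, 130, 17.8, oi_type,
                            frozenset(flags))


def test_exclusions_counts_and_enrollment():
    subjects = ([_subject(i) for i in range(20)]
                + [_subject(20 + i, flags={"poor_image_quality"}) for i in range(7)]
                + [_subject(27 + i, flags={"lost_images"}) for i in range(8)])
    enrolled, report = tc.apply_exclusions(subjects)
    assert report.n_screened == 35
    assert report.n_enrolled == len(enrolled) == 20
    assert report.n_excluded_by_reason == {"poor_image_quality": 7,
                                           "lost_images": 8}


def test_exclusions_empty_and_multi_flag():
    enrolled, report = tc.apply_exclusions([])
    assert (report.n_screened, report.n_excluded, report.n_enrolled) == (0, 0, 0)
    both = [_subject(0, flags={"poor_image_quality", "lost_images"}),
            _subject(1)]
    enrolled, report = tc.apply_exclusions(both)
    assert report.n_enrolled == 1 and report.n_excluded == 1
    assert report.n_excluded_by_reason == {"poor_image_quality": 1,
                                           "lost_images": 1}
    assert report.n_multi_reason == 1


# ---------------------------------------------------------------------------
# Bland-Altman


def test_bland_altman_identical_lists():
    ba = tc.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert ba.mean_difference == 0.0
    assert (ba.loa_lower, ba.loa_upper) == (0.0, 0.0)


def test_bland_altman_hand_computed():
    ba = tc.bland_altman([0.0, 1.0, 3.0], [1.0, 1.0, 2.0])  # diffs -1, 0, 1
    assert ba.mean_difference == pytest.approx(0.0)
    assert ba.sd_difference == pytest.approx(1.0)
    assert ba.loa_lower == pytest.approx(-1.96)
    assert ba.loa_upper == pytest.approx(1.96)


def test_bland_altman_rejects_bad_pairs():
    with pytest.raises(InvalidPairsError):
        tc.bland_altman([1.0], [2.0])
    with pytest.raises(InvalidPairsError):
        tc.bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
                min_size=2, max_size=40))
def test_bland_altman_midpoint_identity(pairs):
    a, b = zip(*pairs)
    ba = tc.bland_altman(a, b)
    midpoint = (ba.loa_lower + ba.loa_upper) / 2.0
    assert midpoint == pytest.approx(ba.mean_difference, abs=1e-9)
    assert ba.loa_lower <= ba.mean_difference <= ba.loa_upper


# ---------------------------------------------------------------------------
# Variance gate and t tests


def test_levene_identical_deviation_pattern_gives_p_one():
    assert tc.levene_center_mean([1, 2, 3], [4, 5, 6]) == pytest.approx(1.0)


def test_levene_detects_unequal_spread():
    assert tc.levene_center_mean([0, 0, 0, 0], [-10, 10, -10, 10]) < 0.05


def test_levene_requires_n_at_least_two():
    with pytest.raises(TrunkCompError):
        tc.levene_center_mean([1.0], [1.0, 2.0])


def test_t_identical_groups_is_null():
    cmp_ = tc.t_test_from_samples([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    assert cmp_.t_statistic == 0.0 and cmp_.p_value == 1.0


def test_t_pooled_equals_welch_for_equal_n_and_sd():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = a + 2.5  # same sample SD, same n
    pooled = tc.t_test_from_samples(a, b, variant="pooled")
    welch = tc.t_test_from_samples(a, b, variant="welch")
    assert pooled.t_statistic == pytest.approx(welch.t_statistic)


def test_t_label_swap_flips_sign_only():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
    ab = tc.t_test_from_samples(a, b)
    ba = tc.t_test_from_samples(b, a)
    assert ab.t_statistic == pytest.approx(-ba.t_statistic)
    assert ab.p_value == pytest.approx(ba.p_value)


def test_t_test_matches_permutation_oracle():
    rng = np.random.default_rng(11)
    a = rng.normal(0.0, 1.0, 18)
    b = rng.normal(0.7, 1.0, 20)
    cmp_ = tc.t_test_from_samples(a, b, variant="pooled")
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = abs(a.mean() - b.mean())
    draws = 20_000
    perm = np.array([rng.permutation(pooled) for _ in range(draws)])
    diffs = np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))
    p_perm = (1 + np.sum(diffs >= observed)) / (draws + 1)
    # permutation p approximates the t p up to Monte-Carlo + exchangeability error
    assert cmp_.p_value == pytest.approx(p_perm, abs=0.03)


def test_summary_t_reproduces_printed_comparisons():
    (m1, s1), (m2, s2) = (reference.MEASUREMENTS[("gmm", "midT4", "area_cm2")][g]
                          for g in ("OI", "control"))
    welch = tc.t_test_from_summary(m1, s1, 20, m2, s2, 40, variant="welch")
    assert round(welch.p_value, 2) == 0.03
    pooled = tc.t_test_from_summary(m1, s1, 20, m2, s2, 40, variant="pooled")
    assert pooled.p_value > 0.05  # only the Welch form matches the report
    auto = tc.t_test_from_summary(m1, s1, 20, m2, s2, 40, variant="auto")
    assert auto.variance_gate == "welch"

    (m1, s1), (m2, s2) = (reference.MEASUREMENTS[("fixed", "midT4", "density_hu")][g]
                          for g in ("OI", "control"))
    assert tc.t_test_from_summary(m1, s1, 20, m2, s2, 40,
                                  variant="pooled").p_value < 0.01


def test_summary_t_equal_means_null():
    cmp_ = tc.t_test_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
    assert cmp_.t_statistic == 0.0 and cmp_.p_value == 1.0


# ---------------------------------------------------------------------------
# Chi-square and ANOVA


def test_chi_square_identical_proportions_is_null():
    chi2, p = tc.chi_square_2x2([[15, 5], [30, 10]])
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_square_closed_form_and_symmetry():
    chi2, _ = tc.chi_square_2x2([[10, 0], [0, 10]])
    assert chi2 == pytest.approx(20.0)
    a = tc.chi_square_2x2([[12, 7], [5, 16]])
    b = tc.chi_square_2x2([[12, 5], [7, 16]])  # transpose
    assert a == pytest.approx(b)


def test_chi_square_rejects_zero_margin():
    with pytest.raises(TrunkCompError):
        tc.chi_square_2x2([[5, 0], [7, 0]])


def test_anova_constant_and_two_group_identity():
    F, _, p = tc.one_way_anova([3.0, 3.0], [3.0, 3.0, 3.0])
    assert (F, p) == (0.0, 1.0)
    rng = np.random.default_rng(4)
    a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 11)
    F, _, _ = tc.one_way_anova(a, b)
    t = tc.t_test_from_samples(a, b, variant="pooled").t_statistic
    assert F == pytest.approx(t ** 2)


def test_anova_matches_direct_decomposition():
    groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0]),
              np.array([5.0, 6.0, 9.0])]
    allv = np.concatenate(groups)
    ss_between = sum(g.size * (g.mean() - allv.mean()) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    F_direct = (ss_between / 2) / (ss_within / (allv.size - 3))
    F, df, _ = tc.one_way_anova(*groups)
    assert F == pytest.approx(F_direct)
    assert df == (2, 5)


# ---------------------------------------------------------------------------
# Table builders on an exactly moment-matched cohort


@pytest.fixture(scope="module")
def reference_cohort():
    """Per-subject tables whose group moments equal the reference summaries."""
    variables = {}
    for (method, level, metric), targets in reference.MEASUREMENTS.items():
        variables[f"{method}_{level}_{metric}"] = targets
    demo = {var: t for var, t in reference.DEMOGRAPHICS.items()}
    groups = {
        g: tc.GroupTargets(n=reference.GROUP_N[g], variables={
            **{k: v[g] for k, v in variables.items()},
            **{k: v[g] for k, v in demo.items()}})
        for g in ("OI", "control")}
    table = tc.generate_cohort(tc.CohortSpec(groups=groups, seed=123))

    subjects, rows = [], []
    for _, row in table.iterrows():
        g = row["group"]
        i = int(row["subject_id"].split("_")[1])
        n_male = reference.SEX_COUNTS[g]["male"]
        subjects.append(tc.SubjectRecord(
            row["subject_id"], g, "male" if i < n_male else "female",
            row["age"], row["weight"], row["height"], row["bmi"],
            ("I" if i < 15 else "III" if i < 17 else "IV") if g == "OI" else "none"))
        for method, level, metric in reference.MEASUREMENTS:
            rows.append({"subject_id": row["subject_id"], "level": level,
                         "method": method, "metric": metric,
                         "value": row[f"{method}_{level}_{metric}"]})
    long = pd.DataFrame(rows)
    measurements = long.pivot_table(
        index=["subject_id", "level", "method"], columns="metric",
        values="value").reset_index()
    measurements["bone_area_cm2"] = 1.0
    measurements["flags"] = ""
    return measurements, subjects


def test_group_comparison_reproduces_printed_summaries(reference_cohort):
    measurements, subjects = reference_cohort
    table = tc.build_group_comparison_table(measurements, subjects)
    row = table[table["variable"] == "T4 muscle density (HU) [fixed]"].iloc[0]
    assert row["oi_summary"] == "41.2 ± 5.5"
    assert row["control_summary"] == "48.0 ± 4.7"
    assert row["p_fmt"] == "< 0.01"
    row = table[table["variable"] == "T4 muscle size (cm2) [gmm]"].iloc[0]
    assert row["oi_summary"] == "110.9 ± 18.4"
    assert row["p_fmt"] == "0.03"  # the Welch branch of the variance gate
    row = table[table["variable"] == "Gender (male/female)"].iloc[0]
    assert row["oi_summary"] == "15/5" and row["control_summary"] == "30/10"
    assert row["statistic"] == pytest.approx(0.0)  # identical 75% male fractions


def test_density_comparisons_below_001_under_both_variants(reference_cohort):
    measurements, subjects = reference_cohort
    for variant in ("pooled", "welch"):
        table = tc.build_group_comparison_table(measurements, subjects,
                                                variant=variant)
        for var in ("T4 muscle density (HU) [fixed]",
                    "T10 muscle density (HU) [fixed]",
                    "T4 muscle density (HU) [gmm]",
                    "T10 muscle density (HU) [gmm]"):
            assert table[table["variable"] == var].iloc[0]["p_value"] < 0.01


def test_method_agreement_table_structure(reference_cohort):
    measurements, subjects = reference_cohort
    table = tc.build_method_agreement_table(measurements)
    assert len(table) == 4
    assert (table["n_pairs"] == 60).all()
    np.testing.assert_allclose(
        (table["loa_lower"] + table["loa_upper"]) / 2,
        table["mean_difference"], atol=1e-9)


def test_agreement_identical_methods_all_zero(reference_cohort):
    measurements, _ = reference_cohort
    cloned = measurements.copy()
    fixed_rows = cloned[cloned["method"] == "fixed"]
    for metric in ("area_cm2", "density_hu"):
        cloned.loc[cloned["method"] == "gmm", metric] = \
            fixed_rows.sort_values(["subject_id", "level"])[metric].to_numpy()
    cloned_sorted = cloned.sort_values(["subject_id", "level", "method"])
    table = tc.build_method_agreement_table(cloned_sorted)
    np.testing.assert_allclose(table["mean_difference"], 0.0, atol=1e-12)
    np.testing.assert_allclose(table["loa_upper"], 0.0, atol=1e-12)


def test_single_group_cohort_flagged(reference_cohort):
    measurements, subjects = reference_cohort
    oi_only = [s for s in subjects if s.group == "OI"]
    table = tc.build_group_comparison_table(measurements, oi_only)
    assert (table["comparison"] == "absent").all()


def test_subgroup_tables_cover_sections(reference_cohort):
    measurements, subjects = reference_cohort
    for method in ("fixed", "gmm"):
        table = tc.build_subgroup_table(measurements, subjects, method)
        assert set(table["section"]) == {"OI_sex", "control_sex", "OI_type"}
        assert ((table["p_value"].dropna() >= 0)
                & (table["p_value"].dropna() <= 1)).all()


def test_p_formatting_convention():
    assert format_p(0.004) == "< 0.01"
    assert format_p(0.0051) == "0.01"
    assert format_p(0.034) == "0.03"
    assert format_p(0.63) == "0.63"
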