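"""Mean (SD) cells and the two-way mixed ANOVA, checked against independent
computations (2x2 algebraic identities and pingouin)."""

import math

import numpy as np
import pytest
from scipy import stats

from visualdata import (
    BenefitDirection,
    ClassificationRule,
    OutcomeSpec,
    StudyDataset,
    SubjectRecord,
    ValidationError,
    format_p,
    format_summary_table,
    mean_sd,
    mixed_anova,
    summary_table,
    summary_to_frame,
)

INC = BenefitDirection.INCREASE_IS_BETTER


def _two_arm_study(pre_a, post_a, pre_b, post_b, arms=("A", "B")):
    outcome = OutcomeSpec(
        name="y", units="", role="primary", benefit_direction=INC,
        rule=ClassificationRule(method="delta_zero"),
    )
    subjects = [
        SubjectRecord(f"{arms[0]}{i:02d}", arms[0], {"y": (p, q)})
        for i, (p, q) in enumerate(zip(pre_a, post_a))
    ] + [
        SubjectRecord(f"{arms[1]}{i:02d}", arms[1], {"y": (p, q)})
        for i, (p, q) in enumerate(zip(pre_b, post_b))
    ]
    return StudyDataset(outcomes=[outcome], subjects=subjects, arm_labels=list(arms))


def _anova_identities(pre_a, post_a, pre_b, post_b):
    """Independent route: in a 2-arm x 2-time design the group effect is a
    one-way ANOVA on subject means, and time/interaction reduce to the
    change scores."""
    m_a = (np.asarray(pre_a) + np.asarray(post_a)) / 2
    m_b = (np.asarray(pre_b) + np.asarray(post_b)) / 2
    d_a = np.asarray(post_a) - np.asarray(pre_a)
    d_b = np.asarray(post_b) - np.asarray(pre_b)
    n1, n2 = len(m_a), len(m_b)
    n = n1 + n2
    m_all = np.concatenate([m_a, m_b])
    grand_m = m_all.mean()
    ss_group = 2 * (n1 * (m_a.mean() - grand_m) ** 2 + n2 * (m_b.mean() - grand_m) ** 2)
    ss_subj = 2 * (((m_a - m_a.mean()) ** 2).sum() + ((m_b - m_b.mean()) ** 2).sum())
    f_group = ss_group / (ss_subj / (n - 2))
    d_all = np.concatenate([d_a, d_b])
    dbar = d_all.mean()
    ss_time = n * dbar**2 / 2
    ss_inter = (n1 * (d_a.mean() - dbar) ** 2 + n2 * (d_b.mean() - dbar) ** 2) / 2
    ss_err = (((d_a - d_a.mean()) ** 2).sum() + ((d_b - d_b.mean()) ** 2).sum()) / 2
    ms_err = ss_err / (n - 2)
    return f_time_group_inter(ss_time, ss_inter, ms_err, f_group)


def f_time_group_inter(ss_time, ss_inter, ms_err, f_group):
    return ss_time / ms_err, f_group, ss_inter / ms_err


def test_mean_sd_textbook_values():
    assert mean_sd([1, 2, 3]) == (2.0, 1.0)


def test_mean_sd_constant_list_has_zero_sd():
    m, sd = mean_sd([4.2, 4.2, 4.2])
    assert (m, sd) == (pytest.approx(4.2), 0.0)


def test_mean_sd_needs_two_values():
    with pytest.raises(ValidationError):
        mean_sd([1.0])


def test_f5_pre_moments_round_to_printed_values(f5_study):
    pre = [s.values["renal_function"][0] for s in f5_study.subjects]
    m, sd = mean_sd(pre)
    assert (round(m, 1), round(sd, 1)) == (97.1, 2.1)


def test_anova_null_case_all_flat():
    """Identical arms with pre == post everywhere: no variance anywhere, all
    F statistics 0 and all p-values 1."""
    vals = [10.0, 11.0, 12.0]
    res = mixed_anova(_two_arm_study(vals, vals, vals, vals), "y")
    assert res.f_time == res.f_group == res.f_interaction == 0.0
    assert res.p_time == res.p_group == res.p_interaction == 1.0


def test_anova_matches_algebraic_identities():
    rng = np.random.default_rng(3)
    for n1, n2 in [(5, 5), (7, 4), (12, 12)]:
        pre_a, post_a = rng.normal(10, 2, n1), rng.normal(11, 2, n1)
        pre_b, post_b = rng.normal(10, 2, n2), rng.normal(10.5, 2, n2)
        res = mixed_anova(_two_arm_study(pre_a, post_a, pre_b, post_b), "y")
        f_time, f_group, f_inter = _anova_identities(pre_a, post_a, pre_b, post_b)
        assert res.f_time == pytest.approx(f_time, rel=1e-10)
        assert res.f_group == pytest.approx(f_group, rel=1e-10)
        assert res.f_interaction == pytest.approx(f_inter, rel=1e-10)


def test_anova_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(7)
    n = 10
    pre_a, post_a = rng.normal(10, 2, n), rng.normal(12, 2, n)
    pre_b, post_b = rng.normal(10, 2, n), rng.normal(10.3, 2, n)
    res = mixed_anova(_two_arm_study(pre_a, post_a, pre_b, post_b), "y")
    rows = []
    for arm, pres, posts in [("A", pre_a, post_a), ("B", pre_b, post_b)]:
        for i, (p, q) in enumerate(zip(pres, posts)):
            rows += [
                {"subj": f"{arm}{i}", "arm": arm, "time": "pre", "y": p},
                {"subj": f"{arm}{i}", "arm": arm, "time": "post", "y": q},
            ]
    aov = pingouin.mixed_anova(
        pd.DataFrame(rows), dv="y", within="time", subject="subj", between="arm"
    ).set_index("Source")
    assert res.f_group == pytest.approx(aov.loc["arm", "F"], rel=1e-9)
    assert res.f_time == pytest.approx(aov.loc["time", "F"], rel=1e-9)
    assert res.f_interaction == pytest.approx(aov.loc["Interaction", "F"], rel=1e-9)
    assert res.p_interaction == pytest.approx(aov.loc["Interaction", "p_unc"], rel=1e-9)


def test_location_invariance():
    rng = np.random.default_rng(5)
    pre_a, post_a = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
    pre_b, post_b = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
    r1 = mixed_anova(_two_arm_study(pre_a, post_a, pre_b, post_b), "y")
    r2 = mixed_anova(
        _two_arm_study(pre_a + 100, post_a + 100, pre_b + 100, post_b + 100), "y"
    )
    assert r1.p_time == pytest.approx(r2.p_time, abs=1e-9)
    assert r1.p_group == pytest.approx(r2.p_group, abs=1e-9)
    assert r1.p_interaction == pytest.approx(r2.p_interaction, abs=1e-9)


def test_listwise_deletion_counts_dropped():
    pre_a, post_a = [1.0, 2.0, 3.0], [2.0, 3.0, math.nan]
    pre_b, post_b = [1.0, 2.0, 4.0], [1.0, 2.5, 4.0]
    res = mixed_anova(_two_arm_study(pre_a, post_a, pre_b, post_b), "y")
    assert res.n_dropped == 1 and res.n_used == 5


def test_anova_requires_two_complete_cases_per_arm():
    study = _two_arm_study([1, 2], [1, math.nan], [1, 2], [2, 3])
    with pytest.raises(ValidationError, match="fewer than 2"):
        mixed_anova(study, "y")


def test_f2_summary_reproduces_printed_cells(f2_study):
    rows = summary_table(f2_study)
    assert [r.outcome for r in rows] == [
        "blood_pressure",
        "heart_rate_variability",
        "arterial_stiffness",
        "endothelial_function",
    ]
    bp = rows[0]
    cells = {
        ("Control", "pre"): (139, 3),
        ("Control", "post"): (137, 2),
        ("Experimental", "pre"): (139, 2),
        ("Experimental", "post"): (134, 2),
    }
    for key, (m, sd) in cells.items():
        got_m, got_sd = bp.cells[key]
        assert round(got_m) == m and round(got_sd) == sd
    assert bp.p_interaction < 0.001


def test_summary_frame_layout(f2_study):
    df = summary_to_frame(summary_table(f2_study), f2_study.arm_labels)
    assert list(df.columns) == [
        "outcome", "units",
        "control_pre_mean", "control_pre_sd", "control_post_mean", "control_post_sd",
        "experimental_pre_mean", "experimental_pre_sd",
        "experimental_post_mean", "experimental_post_sd",
        "p_time", "p_group", "p_interaction",
    ]
    assert len(df) == 4


def test_p_display_convention():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.069) == "0.069"
    text = format_summary_table(
        summary_table_fixture(), ["A", "B"]
    )
    assert "<0.001" in text


def summary_table_fixture():
    rng = np.random.default_rng(2)
    pre_a, post_a = rng.normal(10, 0.1, 20), rng.normal(15, 0.1, 20)
    pre_b, post_b = rng.normal(10, 0.1, 20), rng.normal(10, 0.1, 20)
    return summary_table(_two_arm_study(pre_a, post_a, pre_b, post_b))
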