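"""Cut-off rules: unit examples plus the invariants that hold for any data."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visualdata import (
    BenefitDirection,
    ClassificationRule,
    ConfigError,
    OutcomeSpec,
    ResponseStatus,
    StudyDataset,
    SubjectRecord,
    ValidationError,
    classify_delta_zero,
    classify_quantile,
    classify_risk_threshold,
    classify_study,
    default_threshold_registry,
    delta,
    mdd_threshold,
    response_counts,
)

INC = BenefitDirection.INCREASE_IS_BETTER
DEC = BenefitDirection.DECREASE_IS_BETTER
I, N, W, M = (
    ResponseStatus.IMPROVED,
    ResponseStatus.NO_CHANGE,
    ResponseStatus.WORSENED,
    ResponseStatus.MISSING,
)


def _study_one_outcome(pairs, direction=INC, rule=None, arm="A"):
    rule = rule or ClassificationRule(method="delta_zero")
    outcome = OutcomeSpec(
        name="y", units="", role="primary", benefit_direction=direction, rule=rule
    )
    subjects = [
        SubjectRecord(subject_id=f"S{i:02d}", arm=arm, values={"y": (pre, post)})
        for i, (pre, post) in enumerate(pairs)
    ]
    return StudyDataset(outcomes=[outcome], subjects=subjects, arm_labels=[arm])


# ---------------------------------------------------------------------------
# delta and the two threshold rules


@pytest.mark.parametrize(
    "pre,post,expected",
    [(139, 134, -5), (97.1, 97.1, 0), (8.9, 7.8, pytest.approx(-1.1))],
)
def test_delta_is_post_minus_pre(pre, post, expected):
    assert delta(pre, post) == expected


def test_delta_refuses_missing_values():
    with pytest.raises(ValidationError):
        delta(math.nan, 1.0)


@pytest.mark.parametrize(
    "d,direction,expected",
    [
        (0.0, INC, N),
        (0.0, DEC, N),
        (-5.0, DEC, I),
        (-0.3, INC, W),
        (2.0, INC, I),
        (2.0, DEC, W),
    ],
)
def test_delta_zero_rule(d, direction, expected):
    assert classify_delta_zero(d, direction) is expected


@pytest.mark.parametrize(
    "d,threshold,direction,expected",
    [
        (-5.0, 3.0, DEC, I),
        (-2.0, 3.0, DEC, N),
        (1.0, 1.0, DEC, W),  # boundary |d| == threshold counts as change
        (-3.0, 3.0, DEC, I),  # boundary, benefit side
        (0.0, 3.0, DEC, N),
        (5.5, 5.0, INC, I),
    ],
)
def test_risk_threshold_rule(d, threshold, direction, expected):
    assert classify_risk_threshold(d, threshold, direction) is expected


def test_risk_threshold_requires_positive_threshold():
    with pytest.raises(ConfigError):
        classify_risk_threshold(1.0, 0.0, INC)


def test_default_threshold_registry():
    reg = default_threshold_registry()
    assert reg["blood_pressure"] == 3.0
    assert reg["arterial_stiffness"] == 1.0
    assert reg["flow_mediated_dilation"] == 1.0
    assert "resting_heart_rate" not in reg  # level-based criterion, not a delta
    with pytest.raises(KeyError):
        reg["unknown_marker"]
    reg["custom"] = 2.5  # a fresh copy, freely extensible
    assert "custom" not in default_threshold_registry()


# ---------------------------------------------------------------------------
# quantile rule


def test_quantile_tertiles_of_six_ordered_values():
    out = classify_quantile([-3, -2, -1, 0, 1, 2], k=3, direction=INC)
    assert out == [W, W, N, N, I, I]


def test_quantile_identical_deltas_all_no_change():
    assert classify_quantile([1.5] * 6, k=3, direction=INC) == [N] * 6


def test_quantile_quartiles_of_eight_distinct():
    out = classify_quantile(list(range(8)), k=4, direction=INC)
    assert out.count(I) == 2 and out.count(W) == 2 and out.count(N) == 4


def test_quantile_needs_at_least_k_values():
    with pytest.raises(ValidationError):
        classify_quantile([1.0, 2.0], k=3, direction=INC)


@given(
    data=st.lists(
        st.floats(-100, 100, allow_nan=False), min_size=3, max_size=60, unique=True
    ),
    k=st.sampled_from([3, 4]),
)
@settings(max_examples=200, deadline=None)
def test_quantile_matches_sort_and_slice_oracle(data, k):
    """With k | n and distinct deltas, the extreme groups are exactly the
    lowest and highest n/k values (independent oracle: sort and slice)."""
    n = (len(data) // k) * k
    if n < k:
        return
    data = data[:n]
    out = classify_quantile(data, k=k, direction=INC)
    order = np.argsort(data)
    m = n // k
    expect_w = set(order[:m])
    expect_i = set(order[-m:])
    assert {i for i, s in enumerate(out) if s is W} == expect_w
    assert {i for i, s in enumerate(out) if s is I} == expect_i


# ---------------------------------------------------------------------------
# minimal detectable difference


def test_mdd_closed_form():
    # z_{0.975} * sqrt(2) * 2.0
    assert mdd_threshold(2.0, 0.95) == pytest.approx(5.5439, abs=1e-3)


def test_mdd_limits_and_linearity():
    assert mdd_threshold(1.0, 1e-12) == pytest.approx(0.0, abs=1e-6)
    assert mdd_threshold(4.0, 0.9) == pytest.approx(2 * mdd_threshold(2.0, 0.9))
    with pytest.raises(ConfigError):
        mdd_threshold(-1.0, 0.95)
    with pytest.raises(ConfigError):
        mdd_threshold(1.0, 1.0)


def test_mdd_rule_equals_explicit_risk_threshold():
    """Classifying under mdd is cell-by-cell identical to a risk threshold
    set to mdd_threshold(sem, confidence)."""
    rng = np.random.default_rng(11)
    pairs = [(p, p + d) for p, d in zip(rng.normal(50, 5, 30), rng.normal(0, 6, 30))]
    t = mdd_threshold(2.0, 0.95)
    study_mdd = _study_one_outcome(
        pairs, INC, ClassificationRule(method="mdd", sem=2.0, confidence=0.95)
    )
    study_risk = _study_one_outcome(
        pairs, INC, ClassificationRule(method="risk_threshold", threshold=t)
    )
    assert classify_study(study_mdd).statuses == classify_study(study_risk).statuses


# ---------------------------------------------------------------------------
# whole-study classification and counts


def test_missing_pre_or_post_is_missing_status():
    study = _study_one_outcome([(1.0, math.nan), (math.nan, 2.0), (1.0, 2.0)])
    st_map = classify_study(study).statuses
    assert st_map[("S00", "y")] is M
    assert st_map[("S01", "y")] is M
    assert st_map[("S02", "y")] is I


def test_f5_delta_zero_split(f5_classified):
    counts = response_counts(f5_classified, "Intervention", "renal_function")
    assert (counts.n_improved, counts.n_no_change, counts.n_worsened) == (12, 5, 3)
    assert counts.pct_no_change == 25.0
    assert counts.pct_worsened == 15.0


def test_empty_study_classifies_to_empty_matrix():
    study = _study_one_outcome([])
    assert classify_study(study).statuses == {}


def test_response_counts_unknown_arm_or_outcome(f5_classified):
    with pytest.raises(ValidationError):
        response_counts(f5_classified, "NoSuchArm", "renal_function")
    with pytest.raises(ValidationError):
        response_counts(f5_classified, "Intervention", "nope")


def test_all_missing_arm_counts():
    study = _study_one_outcome([(math.nan, math.nan)] * 4)
    counts = response_counts(classify_study(study), "A", "y")
    assert counts.n_missing == 4
    assert counts.pct_improved == counts.pct_no_change == counts.pct_worsened == 0.0


def test_observed_denominator_option():
    study = _study_one_outcome([(0, 1), (0, 1), (0, -1), (0, math.nan)])
    counts = response_counts(classify_study(study), "A", "y")
    assert counts.pct_improved == 50.0  # 2 of 4 enrolled
    assert counts.pct(I, denominator="observed") == pytest.approx(100 * 2 / 3)


def test_quantile_rule_evaluated_within_arm():
    """Arm A's deltas are all far above arm B's; pooled tertiles would call
    every A subject improved, per-arm tertiles must not."""
    outcome = OutcomeSpec(
        name="y", units="", role="primary", benefit_direction=INC,
        rule=ClassificationRule(method="quantile", k=3),
    )
    subjects = [
        SubjectRecord(f"A{i}", "A", {"y": (0.0, 100.0 + i)}) for i in range(6)
    ] + [SubjectRecord(f"B{i}", "B", {"y": (0.0, float(i))}) for i in range(6)]
    study = StudyDataset(outcomes=[outcome], subjects=subjects, arm_labels=["A", "B"])
    st_map = classify_study(study).statuses
    a_statuses = [st_map[(f"A{i}", "y")] for i in range(6)]
    assert a_statuses.count(I) == 2 and a_statuses.count(W) == 2


# ---------------------------------------------------------------------------
# invariants


@given(
    deltas=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=30),
    threshold=st.floats(0.1, 10, allow_nan=False),
)
@settings(max_examples=150, deadline=None)
def test_direction_antisymmetry(deltas, threshold):
    """Flipping the benefit direction swaps IMPROVED and WORSENED and leaves
    NO_CHANGE alone, for both delta-zero and risk-threshold rules."""
    swap = {I: W, W: I, N: N}
    for d in deltas:
        assert classify_delta_zero(d, DEC) is swap[classify_delta_zero(d, INC)]
        assert (
            classify_risk_threshold(d, threshold, DEC)
            is swap[classify_risk_threshold(d, threshold, INC)]
        )


@given(
    deltas=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=30),
    t1=st.floats(0.1, 10),
    t2=st.floats(0.1, 10),
)
@settings(max_examples=150, deadline=None)
def test_threshold_monotonicity(deltas, t1, t2):
    """Raising the risk threshold never increases the number of changers."""
    lo, hi = sorted([t1, t2])
    changed_lo = sum(
        classify_risk_threshold(d, lo, INC) is not N for d in deltas
    )
    changed_hi = sum(
        classify_risk_threshold(d, hi, INC) is not N for d in deltas
    )
    assert changed_hi <= changed_lo


def test_counts_conserve_arm_size(f2_classified, f2_study):
    for arm in f2_study.arm_labels:
        size = len(f2_study.subjects_in_arm(arm))
        for o in f2_study.outcomes:
            assert response_counts(f2_classified, arm, o.name).n_total == size
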