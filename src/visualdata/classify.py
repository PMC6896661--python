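"""Cut-off rules turning per-subject pre/post deltas into response statuses.

Four rules are supported:

* ``delta_zero`` — any non-zero change in the benefit direction is a
  response; the rule deliberately ignores measurement error.
* ``risk_threshold`` — a change of at least a clinically anchored magnitude
  (e.g. 3 mmHg systolic blood pressure) counts; |delta| exactly equal to the
  threshold counts as a change (inclusive boundary).
* ``quantile`` — subjects in the extreme tertile/quartile of their arm's
  delta distribution are responders (or worseners, on the other tail).
* ``mdd`` — a risk threshold set to the minimal detectable difference of a
  change score, z_{(1+c)/2} * sqrt(2) * SEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import (
    BenefitDirection,
    ClassificationRule,
    ClassifiedStudy,
    ConfigError,
    ResponseStatus,
    StudyDataset,
    ValidationError,
    is_missing,
)

__all__ = [
    "delta",
    "classify_delta_zero",
    "classify_risk_threshold",
    "default_threshold_registry",
    "classify_quantile",
    "mdd_threshold",
    "classify_study",
    "response_counts",
    "all_response_counts",
    "ResponseCounts",
]


def delta(pre: float, post: float) -> float:
    """Change score post - pre. Both values must be present."""
    if is_missing(pre) or is_missing(post):
        raise ValidationError(
            "delta requires both pre and post; classify missing cells as "
            "MISSING before computing deltas"
        )
    return post - pre


def classify_delta_zero(d: float, direction: BenefitDirection) -> ResponseStatus:
    """Any non-zero delta is a response; only an exact zero is NO_CHANGE."""
    if not math.isfinite(d):
        raise ValidationError(f"delta must be finite, got {d}")
    if d == 0:
        return ResponseStatus.NO_CHANGE
    return (
        ResponseStatus.IMPROVED
        if d * direction.sign > 0
        else ResponseStatus.WORSENED
    )


def classify_risk_threshold(
    d: float, threshold: float, direction: BenefitDirection
) -> ResponseStatus:
    """|delta| >= threshold (inclusive) is a change, signed by direction."""
    if not threshold > 0:
        raise ConfigError(f"risk threshold must be > 0, got {threshold}")
    if not math.isfinite(d):
        raise ValidationError(f"delta must be finite, got {d}")
    if abs(d) < threshold:
        return ResponseStatus.NO_CHANGE
    return (
        ResponseStatus.IMPROVED
        if d * direction.sign > 0
        else ResponseStatus.WORSENED
    )


#: Clinically anchored delta cut-offs from longitudinal risk studies.
#: Resting heart rate's published 75 bpm criterion is a level, not a change
#: score, so it has no entry here; callers must supply an explicit threshold.
_DEFAULT_THRESHOLDS = {
    "blood_pressure": 3.0,  # mmHg
    "arterial_stiffness": 1.0,  # m/s (pulse-wave velocity)
    "flow_mediated_dilation": 1.0,  # %
}


def default_threshold_registry() -> dict[str, float]:
    """A fresh, user-extensible copy of the built-in delta-threshold registry."""
    return dict(_DEFAULT_THRESHOLDS)


def classify_quantile(
    deltas: Sequence[float], k: int, direction: BenefitDirection
) -> list[ResponseStatus]:
    """Split deltas into k equal-probability groups; extremes are responses.

    Sample quantiles use linear interpolation (the inclusive definition). A
    delta lying exactly on a cut goes to the more central group, so an
    all-identical sample is entirely NO_CHANGE.  Output order matches input
    order.
    """
    if k not in (3, 4):
        raise ConfigError(f"quantile rule requires k in {{3, 4}}, got {k}")
    arr = np.asarray(deltas, dtype=float)
    if arr.ndim != 1 or arr.size < k:
        raise ValidationError(
            f"quantile rule needs at least k={k} deltas, got {arr.size}"
        )
    if np.isnan(arr).any():
        raise ValidationError("quantile rule takes non-missing deltas only")
    lo_cut = float(np.quantile(arr, 1.0 / k))
    hi_cut = float(np.quantile(arr, (k - 1.0) / k))
    upper = ResponseStatus.IMPROVED if direction.sign > 0 else ResponseStatus.WORSENED
    lower = ResponseStatus.WORSENED if direction.sign > 0 else ResponseStatus.IMPROVED
    out = []
    for d in arr:
        if d > hi_cut:
            out.append(upper)
        elif d < lo_cut:
            out.append(lower)
        else:
            out.append(ResponseStatus.NO_CHANGE)
    return out


def mdd_threshold(sem: float, confidence: float) -> float:
    """Minimal detectable difference of a pre/post change score.

    ``z * sqrt(2) * SEM`` with z the two-sided standard-normal quantile at
    the given confidence; the sqrt(2) propagates the measurement error of
    two occasions into the difference.
    """
    if not sem > 0:
        raise ConfigError(f"sem must be > 0, got {sem}")
    if not 0 < confidence < 1:
        raise ConfigError(f"confidence must lie in (0, 1), got {confidence}")
    z = stats.norm.ppf((1.0 + confidence) / 2.0)
    return float(z * math.sqrt(2.0) * sem)


def _rule_threshold(rule: ClassificationRule) -> float:
    if rule.method == "risk_threshold":
        return rule.threshold
    return mdd_threshold(rule.effective_sem, rule.confidence)


def classify_study(study: StudyDataset) -> ClassifiedStudy:
    """Apply each outcome's rule to every subject.

    Cells with a missing pre or post value are MISSING and no rule is
    evaluated for them.  Quantile rules pool non-missing deltas within arm
    by default (``quantile_scope: study`` pools across arms).
    """
    statuses: dict[tuple[str, str], ResponseStatus] = {}
    for outcome in study.outcomes:
        rule = outcome.rule
        direction = outcome.benefit_direction
        cells: dict[str, float] = {}  # subject_id -> delta, non-missing only
        for s in study.subjects:
            pre, post = s.pair(outcome.name)
            if is_missing(pre) or is_missing(post):
                statuses[(s.subject_id, outcome.name)] = ResponseStatus.MISSING
            else:
                cells[s.subject_id] = delta(pre, post)

        if rule.method == "quantile":
            if rule.quantile_scope == "study":
                groups = [list(cells.items())]
            else:
                arm_of = {s.subject_id: s.arm for s in study.subjects}
                groups = [
                    [(sid, d) for sid, d in cells.items() if arm_of[sid] == arm]
                    for arm in study.arm_labels
                ]
            for group in groups:
                if not group:
                    continue
                if len(group) < rule.k:
                    raise ValidationError(
                        f"outcome {outcome.name!r}: quantile rule needs at least "
                        f"k={rule.k} non-missing deltas per scope, got {len(group)}"
                    )
                verdicts = classify_quantile(
                    [d for _, d in group], rule.k, direction
                )
                for (sid, _), st in zip(group, verdicts):
                    statuses[(sid, outcome.name)] = st
        elif rule.method == "delta_zero":
            for sid, d in cells.items():
                statuses[(sid, outcome.name)] = classify_delta_zero(d, direction)
        else:  # risk_threshold or mdd
            threshold = _rule_threshold(rule)
            for sid, d in cells.items():
                statuses[(sid, outcome.name)] = classify_risk_threshold(
                    d, threshold, direction
                )
    return ClassifiedStudy(statuses=statuses, source=study)


@dataclass(frozen=True)
class ResponseCounts:
    """Per-arm, per-outcome response tally.

    Percentages use the full arm size (including MISSING subjects) as the
    denominator, matching the convention of quoting "25% (n=5)" of all
    enrolled subjects.
    """

    arm: str
    outcome: str
    n_improved: int
    n_no_change: int
    n_worsened: int
    n_missing: int

    @property
    def n_total(self) -> int:
        return self.n_improved + self.n_no_change + self.n_worsened + self.n_missing

    def _pct(self, n: int, denominator: str = "all") -> float:
        denom = self.n_total if denominator == "all" else self.n_total - self.n_missing
        return 100.0 * n / denom if denom else 0.0

    @property
    def pct_improved(self) -> float:
        return self._pct(self.n_improved)

    @property
    def pct_no_change(self) -> float:
        return self._pct(self.n_no_change)

    @property
    def pct_worsened(self) -> float:
        return self._pct(self.n_worsened)

    def pct(self, status: ResponseStatus, denominator: str = "all") -> float:
        n = {
            ResponseStatus.IMPROVED: self.n_improved,
            ResponseStatus.NO_CHANGE: self.n_no_change,
            ResponseStatus.WORSENED: self.n_worsened,
            ResponseStatus.MISSING: self.n_missing,
        }[status]
        return self._pct(n, denominator)


def response_counts(
    classified: ClassifiedStudy, arm: str, outcome: str
) -> ResponseCounts:
    """Tally statuses for one arm and one outcome."""
    study = classified.source
    study.outcome(outcome)  # raises on unknown outcome
    members = study.subjects_in_arm(arm)  # raises on unknown arm
    tally = {st: 0 for st in ResponseStatus}
    for s in members:
        tally[classified.statuses[(s.subject_id, outcome)]] += 1
    return ResponseCounts(
        arm=arm,
        outcome=outcome,
        n_improved=tally[ResponseStatus.IMPROVED],
        n_no_change=tally[ResponseStatus.NO_CHANGE],
        n_worsened=tally[ResponseStatus.WORSENED],
        n_missing=tally[ResponseStatus.MISSING],
    )


def all_response_counts(classified: ClassifiedStudy) -> list[ResponseCounts]:
    """Counts for every arm x outcome combination, in config order."""
    study = classified.source
    return [
        response_counts(classified, arm, o.name)
        for arm in study.arm_labels
        for o in study.outcomes
    ]
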