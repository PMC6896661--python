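"""Conventional group x time summary: mean (SD) cells and mixed-design ANOVA.

This is the presentation the glyph chart is contrasted against: per-arm,
per-timepoint means with standard deviations, plus time, group and
interaction p-values from a two-way mixed ANOVA (between factor: arm;
within factor: time), computed directly from sums of squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import StudyDataset, ValidationError, is_missing

__all__ = [
    "mean_sd",
    "mixed_anova",
    "paired_ttest",
    "summary_table",
    "summary_to_frame",
    "write_summary_csv",
    "format_summary_table",
    "format_p",
    "SummaryRow",
    "MixedAnovaResult",
]

logger = logging.getLogger(__name__)


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    Missing values must be excluded by the caller; fewer than two values
    leave the SD undefined and raise.
    """
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("mean_sd takes non-missing values only")
    if arr.size < 2:
        raise ValidationError(
            f"sample SD is undefined for {arr.size} value(s); need at least 2"
        )
    return float(arr.mean()), float(arr.std(ddof=1))


@dataclass(frozen=True)
class MixedAnovaResult:
    """F statistics, degrees of freedom and p-values of a 2-arm x 2-time design."""

    f_time: float
    f_group: float
    f_interaction: float
    p_time: float
    p_group: float
    p_interaction: float
    df_effect: int  # 1 for every effect in the 2 x 2 design
    df_between_error: int  # subjects within groups
    df_within_error: int  # (subjects within groups) x (times - 1)
    n_used: int
    n_dropped: int


def _f_p(ss_effect: float, df_effect: int, ss_error: float, df_error: int
         ) -> tuple[float, float]:
    # Degenerate data: no error variance. A zero effect over zero error is a
    # perfectly null F (p = 1); a positive effect over zero error is infinitely
    # significant (p = 0).
    ms_error = ss_error / df_error
    if ms_error == 0:
        return (0.0, 1.0) if ss_effect <= 1e-12 else (math.inf, 0.0)
    f = (ss_effect / df_effect) / ms_error
    p = float(stats.f.sf(f, df_effect, df_error))
    return float(f), p


def mixed_anova(study: StudyDataset, outcome: str) -> MixedAnovaResult:
    """Two-way mixed ANOVA for one outcome (between: arm; within: time).

    Subjects with a missing pre or post value for this outcome are dropped
    (listwise deletion per outcome); the design stays exact because every
    retained subject contributes to both timepoints, which keeps arm and
    time orthogonal even with unequal arm sizes.
    """
    study.outcome(outcome)
    if len(study.arm_labels) != 2:
        raise ValidationError(
            f"mixed ANOVA requires exactly 2 arms, study has {len(study.arm_labels)}"
        )
    pre_by_arm: dict[str, list[float]] = {a: [] for a in study.arm_labels}
    post_by_arm: dict[str, list[float]] = {a: [] for a in study.arm_labels}
    n_dropped = 0
    for s in study.subjects:
        pre, post = s.pair(outcome)
        if is_missing(pre) or is_missing(post):
            n_dropped += 1
            continue
        pre_by_arm[s.arm].append(pre)
        post_by_arm[s.arm].append(post)
    if n_dropped:
        logger.info(
            "mixed_anova(%s): dropped %d subject(s) with missing data", outcome,
            n_dropped,
        )
    for arm in study.arm_labels:
        if len(pre_by_arm[arm]) < 2:
            raise ValidationError(
                f"outcome {outcome!r}: arm {arm!r} has fewer than 2 complete cases"
            )

    # y[arm] is an (n_j, 2) matrix: columns pre, post.
    y = {
        arm: np.column_stack([pre_by_arm[arm], post_by_arm[arm]])
        for arm in study.arm_labels
    }
    n_j = {arm: y[arm].shape[0] for arm in study.arm_labels}
    n = sum(n_j.values())
    all_obs = np.concatenate([y[arm].ravel() for arm in study.arm_labels])
    grand = all_obs.mean()

    ss_total = float(((all_obs - grand) ** 2).sum())
    subj_means = np.concatenate([y[arm].mean(axis=1) for arm in study.arm_labels])
    ss_between_subj = float(2.0 * ((subj_means - grand) ** 2).sum())
    ss_group = float(
        2.0 * sum(n_j[a] * (y[a].mean() - grand) ** 2 for a in study.arm_labels)
    )
    ss_subj_within = ss_between_subj - ss_group

    time_means = (
        sum(n_j[a] * y[a].mean(axis=0) for a in study.arm_labels) / n
    )  # length-2 vector of weighted pre/post means
    ss_time = float(n * ((time_means - grand) ** 2).sum())
    ss_cells = float(
        sum(
            n_j[a] * ((y[a].mean(axis=0) - grand) ** 2).sum()
            for a in study.arm_labels
        )
    )
    ss_interaction = ss_cells - ss_group - ss_time
    ss_within_error = ss_total - ss_cells - ss_subj_within

    # Sums of squares are differences of large numbers; tiny negatives are
    # floating-point residue, not signal.
    ss_interaction = max(ss_interaction, 0.0)
    ss_within_error = max(ss_within_error, 0.0)
    ss_subj_within = max(ss_subj_within, 0.0)

    df_between_error = n - 2
    df_within_error = n - 2
    f_group, p_group = _f_p(ss_group, 1, ss_subj_within, df_between_error)
    f_time, p_time = _f_p(ss_time, 1, ss_within_error, df_within_error)
    f_inter, p_inter = _f_p(ss_interaction, 1, ss_within_error, df_within_error)
    return MixedAnovaResult(
        f_time=f_time,
        f_group=f_group,
        f_interaction=f_inter,
        p_time=p_time,
        p_group=p_group,
        p_interaction=p_inter,
        df_effect=1,
        df_between_error=df_between_error,
        df_within_error=df_within_error,
        n_used=n,
        n_dropped=n_dropped,
    )


def paired_ttest(study: StudyDataset, outcome: str) -> tuple[float, float]:
    """Paired t-test of post vs pre over all complete cases (t, p).

    The conventional single-arm analysis an individual-response chart is
    contrasted with.
    """
    study.outcome(outcome)
    pre, post = [], []
    for s in study.subjects:
        a, b = s.pair(outcome)
        if is_missing(a) or is_missing(b):
            continue
        pre.append(a)
        post.append(b)
    if len(pre) < 2:
        raise ValidationError(
            f"outcome {outcome!r}: paired t-test needs at least 2 complete cases"
        )
    t, p = stats.ttest_rel(post, pre)
    return float(t), float(p)


@dataclass(frozen=True)
class SummaryRow:
    """One outcome's summary: mean/SD per (arm, time) cell and three p-values."""

    outcome: str
    units: str
    cells: dict[tuple[str, str], tuple[float, float]]  # (arm, "pre"/"post") -> (mean, sd)
    p_time: float
    p_group: float
    p_interaction: float


def summary_table(study: StudyDataset) -> list[SummaryRow]:
    """One SummaryRow per outcome, in config order.

    Cell moments are computed per arm and timepoint over the values observed
    at that timepoint; the ANOVA itself uses complete cases only.
    """
    if len(study.arm_labels) < 2:
        raise ValidationError("summary_table requires at least 2 arms")
    rows = []
    for o in study.outcomes:
        cells: dict[tuple[str, str], tuple[float, float]] = {}
        for arm in study.arm_labels:
            members = study.subjects_in_arm(arm)
            pre = [s.pair(o.name)[0] for s in members]
            post = [s.pair(o.name)[1] for s in members]
            pre = [v for v in pre if not is_missing(v)]
            post = [v for v in post if not is_missing(v)]
            cells[(arm, "pre")] = mean_sd(pre)
            cells[(arm, "post")] = mean_sd(post)
        res = mixed_anova(study, o.name)
        rows.append(
            SummaryRow(
                outcome=o.name,
                units=o.units,
                cells=cells,
                p_time=res.p_time,
                p_group=res.p_group,
                p_interaction=res.p_interaction,
            )
        )
    return rows


def summary_to_frame(rows: Sequence[SummaryRow], arm_labels: Sequence[str]
                     ) -> pd.DataFrame:
    """Flatten rows to a DataFrame: one column per mean/sd cell plus p-values."""
    records = []
    for r in rows:
        rec: dict[str, object] = {"outcome": r.outcome, "units": r.units}
        for arm in arm_labels:
            key = arm.lower().replace(" ", "_")
            for time in ("pre", "post"):
                m, sd = r.cells[(arm, time)]
                rec[f"{key}_{time}_mean"] = m
                rec[f"{key}_{time}_sd"] = sd
        rec["p_time"] = r.p_time
        rec["p_group"] = r.p_group
        rec["p_interaction"] = r.p_interaction
        records.append(rec)
    return pd.DataFrame(records)


def write_summary_csv(rows: Sequence[SummaryRow], arm_labels: Sequence[str],
                      path: str | Path) -> None:
    summary_to_frame(rows, arm_labels).to_csv(path, index=False)


def format_p(p: float) -> str:
    """Display convention: values below 0.001 print as '<0.001'."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_summary_table(rows: Sequence[SummaryRow], arm_labels: Sequence[str],
                         decimals: int = 1) -> str:
    """Aligned text table in the conventional journal layout."""
    header = ["Variable"]
    for arm in arm_labels:
        header += [f"{arm} pre", f"{arm} post"]
    header += ["Time effect", "Group effect", "Interaction effect"]
    lines = [header]
    for r in rows:
        line = [f"{r.outcome}" + (f", {r.units}" if r.units else "")]
        for arm in arm_labels:
            for time in ("pre", "post"):
                m, sd = r.cells[(arm, time)]
                line.append(f"{m:.{decimals}f} ({sd:.{decimals}f})")
        line += [format_p(r.p_time), format_p(r.p_group), format_p(r.p_interaction)]
        lines.append(line)
    widths = [max(len(row[i]) for row in lines) for i in range(len(header))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in lines
    )
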