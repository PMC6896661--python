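"""Synthetic two-timepoint trial generator and packaged example studies.

The generator draws baseline values from a normal distribution, then
constructs post values so that three things hold simultaneously, by
construction rather than by luck:

* the per-arm responder mix (improved / no change / worsened / missing)
  under the outcome's own classification rule is hit exactly;
* the realized pre and post mean/SD round to the requested targets at their
  printed precision (the pre moments are matched exactly by an affine
  rescale; the post moments by an affine rescale of the unconstrained
  values, with subjects that would cross their class boundary clipped to it
  and pinned, then re-solving until the remaining free values absorb the
  targets exactly);
* everything is a pure function of the seed.

Statuses are allocated to subjects by baseline rank: the class whose change
window points upward gets the lowest baselines and vice versa.  This mimics
regression to the mean and is also what makes tight printed moments
feasible at all — a subject asked to worsen from an already-high baseline
would blow up the post-value spread.

Three packaged studies reconstruct the worked examples the package's
documentation walks through: a 2x40-subject four-outcome trial (``f2``), a
2x40 "statistically significant but not clinically meaningful" contrast
(``f4``), and a 20-subject single-arm renal-function study with a 12/5/3
improved/no-change/worsened split (``f5``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classify import classify_study, mdd_threshold
from .model import (
    BenefitDirection,
    ClassificationRule,
    ConstraintError,
    OutcomeSpec,
    ResponseStatus,
    StudyDataset,
    SubjectRecord,
)

__all__ = [
    "ResponderMix",
    "MomentTargets",
    "OutcomeGenSpec",
    "GeneratorSpec",
    "generate_study",
    "fixture_f2",
    "fixture_f4",
    "fixture_f5",
    "fixture_spec_f2",
    "fixture_spec_f4",
    "fixture_spec_f5",
    "example_single_subject",
]


@dataclass(frozen=True)
class ResponderMix:
    """Requested per-arm split of subjects by response class."""

    n_improved: int
    n_no_change: int
    n_worsened: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_improved", "n_no_change", "n_worsened", "n_missing"):
            if getattr(self, name) < 0:
                raise ConstraintError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n_improved + self.n_no_change + self.n_worsened + self.n_missing


@dataclass(frozen=True)
class MomentTargets:
    """Printed pre/post moments for one arm; ``decimals`` is their precision.

    ``pre_post_corr`` sets the test-retest correlation the initial post
    draws aim for; repeated clinical measures typically correlate 0.6-0.8
    across occasions, and an uncorrelated draw would inflate the change-score
    spread far beyond anything a real trial shows.
    """

    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    decimals: int = 1
    pre_post_corr: float = 0.7

    def __post_init__(self) -> None:
        if self.pre_sd < 0 or self.post_sd < 0:
            raise ConstraintError("target SDs must be non-negative")
        if not -1.0 < self.pre_post_corr < 1.0:
            raise ConstraintError("pre_post_corr must lie in (-1, 1)")


@dataclass(frozen=True)
class OutcomeGenSpec:
    """One outcome's generation request: rule + per-arm targets and mixes."""

    outcome: OutcomeSpec
    targets: dict[str, MomentTargets]
    mix: dict[str, ResponderMix]


@dataclass(frozen=True)
class GeneratorSpec:
    """A full synthetic study request; a pure function of ``seed``."""

    arm_sizes: dict[str, int]
    outcomes: list[OutcomeGenSpec]
    seed: int
    id_prefix: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for og in self.outcomes:
            if og.outcome.rule.method == "quantile":
                raise ConstraintError(
                    f"outcome {og.outcome.name!r}: a responder mix cannot be "
                    "enforced under a quantile rule (the rule's counts are set "
                    "by k, not by the data)"
                )
            for arm, n in self.arm_sizes.items():
                if arm not in og.targets or arm not in og.mix:
                    raise ConstraintError(
                        f"outcome {og.outcome.name!r}: no targets/mix for arm {arm!r}"
                    )
                if og.mix[arm].total != n:
                    raise ConstraintError(
                        f"outcome {og.outcome.name!r}, arm {arm!r}: responder mix "
                        f"sums to {og.mix[arm].total}, arm size is {n}"
                    )


def _affine_match(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Rescale so the sample mean/SD (ddof=1) equal the targets exactly."""
    cur_sd = values.std(ddof=1)
    if cur_sd < 1e-12:
        if sd > 0:
            raise ConstraintError("cannot spread identical draws to a positive SD")
        return np.full_like(values, mean)
    return (values - values.mean()) / cur_sd * sd + mean


def _rule_threshold(rule: ClassificationRule) -> float:
    if rule.method == "delta_zero":
        return 0.0
    if rule.method == "risk_threshold":
        return rule.threshold
    return mdd_threshold(rule.effective_sem, rule.confidence)


# class codes used internally during generation
_IMP, _NC, _WOR, _MIS = 0, 1, 2, 3
_CODE_TO_STATUS = {
    _IMP: ResponseStatus.IMPROVED,
    _NC: ResponseStatus.NO_CHANGE,
    _WOR: ResponseStatus.WORSENED,
    _MIS: ResponseStatus.MISSING,
}


def _delta_windows(
    codes: np.ndarray, threshold: float, sign: int, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject feasible [lo, hi] window for the delta, by class."""
    lo = np.full(codes.shape, -np.inf)
    hi = np.full(codes.shape, np.inf)
    change = threshold if threshold > 0 else eps
    guard = 1e-9 * max(1.0, change)
    imp, nc, wor = codes == _IMP, codes == _NC, codes == _WOR
    if sign > 0:
        lo[imp] = change + guard
        hi[wor] = -change - guard
    else:
        hi[imp] = -change - guard
        lo[wor] = change + guard
    if threshold > 0:
        lo[nc] = -(threshold - guard) + 0.0
        hi[nc] = threshold - guard
    else:  # delta-zero: no change means exactly zero
        lo[nc] = 0.0
        hi[nc] = 0.0
    return lo, hi


def _solve_post(
    rng: np.random.Generator,
    pre: np.ndarray,
    codes: np.ndarray,
    targets: MomentTargets,
    threshold: float,
    sign: int,
    outcome: str,
    arm: str,
) -> np.ndarray:
    """Construct post values hitting the moments under the class windows."""
    n = pre.size
    observed = codes != _MIS
    n_obs = int(observed.sum())
    post = np.full(n, np.nan)
    if n_obs == 0:
        return post
    if n_obs < 2:
        raise ConstraintError(
            f"{outcome!r}/{arm!r}: need at least 2 non-missing subjects"
        )
    m2, s2 = targets.post_mean, targets.post_sd
    eps = 0.01 * max(targets.pre_sd, s2, 1e-6)
    lo, hi = _delta_windows(codes, threshold, sign, eps)
    jitter = 0.05 * max(threshold, s2, eps)

    def clamp(idx: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Pull deltas into their windows, nudged off the boundary."""
        j = np.abs(rng.normal(0.0, jitter, size=idx.size))
        width = hi[idx] - lo[idx]
        j = np.minimum(j, np.where(np.isfinite(width), width / 2, np.inf))
        out = d.copy()
        low = d < lo[idx]
        high = d > hi[idx]
        out[low] = lo[idx][low] + j[low]
        out[high] = hi[idx][high] - j[high]
        return out

    # initial guess: post regresses on pre with the target test-retest
    # correlation, then gets clamped into each subject's class window
    obs_idx = np.flatnonzero(observed)
    rho = targets.pre_post_corr
    beta = rho * s2 / targets.pre_sd if targets.pre_sd > 0 else 0.0
    sigma_e = max(s2 * math.sqrt(1.0 - rho**2), eps)
    d0 = (
        m2
        + beta * (pre[obs_idx] - targets.pre_mean)
        + rng.normal(0.0, sigma_e, size=obs_idx.size)
        - pre[obs_idx]
    )
    post[obs_idx] = pre[obs_idx] + clamp(obs_idx, d0)

    pinned = observed & (codes == _NC) & (threshold == 0.0)
    post[pinned] = pre[pinned]  # delta-zero no-change: post equals pre exactly

    for _ in range(n_obs + 5):
        free_idx = np.flatnonzero(observed & ~pinned)
        if free_idx.size == 0:
            break
        pin_idx = np.flatnonzero(pinned)
        s_p = post[pin_idx].sum()
        a_p = ((post[pin_idx] - m2) ** 2).sum()
        budget = (n_obs - 1) * s2 ** 2
        if free_idx.size == 1:
            post[free_idx] = n_obs * m2 - s_p
        else:
            mu_f = (n_obs * m2 - s_p) / free_idx.size
            var_f = (budget - a_p - free_idx.size * (mu_f - m2) ** 2) / (
                free_idx.size - 1
            )
            if var_f < -1e-9:
                raise ConstraintError(
                    f"{outcome!r}/{arm!r}: post moments mean={m2}, sd={s2} are "
                    f"infeasible for the requested mix under threshold "
                    f"{threshold:g} — the boundary-pinned subjects already "
                    f"spread wider than the target SD allows"
                )
            var_f = max(var_f, 0.0)
            vals = post[free_idx]
            spread = vals.std(ddof=1)
            z = (
                (vals - vals.mean()) / spread
                if spread > 1e-12
                else _standardized_noise(rng, free_idx.size)
            )
            post[free_idx] = mu_f + math.sqrt(var_f) * z
        d = post[free_idx] - pre[free_idx]
        bad = (d < lo[free_idx]) | (d > hi[free_idx])
        if not bad.any():
            break
        bad_idx = free_idx[bad]
        post[bad_idx] = pre[bad_idx] + clamp(bad_idx, d[bad])
        pinned[bad_idx] = True
    # final feasibility pass (covers the all-pinned exit)
    d_all = post[obs_idx] - pre[obs_idx]
    if ((d_all < lo[obs_idx]) | (d_all > hi[obs_idx])).any():
        raise ConstraintError(
            f"{outcome!r}/{arm!r}: could not satisfy the class windows"
        )
    half_unit = 0.5 * 10.0 ** (-targets.decimals)
    realized_m, realized_s = post[obs_idx].mean(), post[obs_idx].std(ddof=1)
    if abs(realized_m - m2) >= half_unit or abs(realized_s - s2) >= half_unit:
        raise ConstraintError(
            f"{outcome!r}/{arm!r}: realized post moments ({realized_m:.4f}, "
            f"{realized_s:.4f}) do not round to the targets ({m2}, {s2})"
        )
    return post


def _standardized_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    z = rng.standard_normal(n)
    return (z - z.mean()) / z.std(ddof=1)


def _assign_codes(
    rng: np.random.Generator, pre: np.ndarray, mix: ResponderMix, sign: int
) -> np.ndarray:
    """Allocate classes to subjects by baseline rank (see module docstring).

    With ``increase_is_better`` the improvers get the lowest baselines and
    the worseners the highest; reversed otherwise.  Missing subjects are a
    uniform random subset.
    """
    n = pre.size
    codes = np.empty(n, dtype=int)
    all_idx = np.arange(n)
    mis = rng.choice(all_idx, size=mix.n_missing, replace=False)
    codes[mis] = _MIS
    rest = np.setdiff1d(all_idx, mis)
    rest = rest[np.argsort(pre[rest], kind="stable")]
    if sign > 0:
        blocks = [(_IMP, mix.n_improved), (_NC, mix.n_no_change), (_WOR, mix.n_worsened)]
    else:
        blocks = [(_WOR, mix.n_worsened), (_NC, mix.n_no_change), (_IMP, mix.n_improved)]
    pos = 0
    for code, count in blocks:
        codes[rest[pos : pos + count]] = code
        pos += count
    return codes


def generate_study(spec: GeneratorSpec) -> StudyDataset:
    """Materialize a GeneratorSpec into a StudyDataset.

    Deterministic in ``spec.seed``; raises ConstraintError when the request
    is internally inconsistent (e.g. a post mean that cannot be reached
    without crossing a class boundary within the target SD).
    """
    arm_labels = list(spec.arm_sizes)
    prefixes = spec.id_prefix or {}
    ids: dict[str, list[str]] = {}
    for arm, n in spec.arm_sizes.items():
        prefix = prefixes.get(arm, arm[:1].upper())
        width = max(2, len(str(n)))
        ids[arm] = [f"{prefix}{i + 1:0{width}d}" for i in range(n)]

    values: dict[str, dict[str, tuple[float, float]]] = {
        sid: {} for arm in arm_labels for sid in ids[arm]
    }
    intended: dict[tuple[str, str], ResponseStatus] = {}
    for oi, og in enumerate(spec.outcomes):
        rule = og.outcome.rule
        threshold = _rule_threshold(rule)
        sign = og.outcome.benefit_direction.sign
        for ai, arm in enumerate(arm_labels):
            rng = np.random.default_rng([spec.seed % (2**31), oi, ai])
            n = spec.arm_sizes[arm]
            targets = og.targets[arm]
            pre = _affine_match(
                rng.standard_normal(n), targets.pre_mean, targets.pre_sd
            )
            codes = _assign_codes(rng, pre, og.mix[arm], sign)
            post = _solve_post(
                rng, pre, codes, targets, threshold, sign, og.outcome.name, arm
            )
            for sid, p, q, c in zip(ids[arm], pre, post, codes):
                values[sid][og.outcome.name] = (float(p), float(q))
                intended[(sid, og.outcome.name)] = _CODE_TO_STATUS[c]

    subjects = [
        SubjectRecord(subject_id=sid, arm=arm, values=values[sid])
        for arm in arm_labels
        for sid in ids[arm]
    ]
    study = StudyDataset(
        outcomes=[og.outcome for og in spec.outcomes],
        subjects=subjects,
        arm_labels=arm_labels,
    )
    # the generator's contract: the rules reproduce the requested mix exactly
    realized = classify_study(study).statuses
    for key, want in intended.items():
        if realized[key] is not want:
            raise ConstraintError(
                f"generation drifted across a rule boundary at {key}: "
                f"wanted {want.value}, classified {realized[key].value}"
            )
    return study


# ---------------------------------------------------------------------------
# Packaged example studies


def fixture_spec_f5(seed: int = 5) -> GeneratorSpec:
    """20-subject single-arm renal-function study, delta-zero 12/5/3 split."""
    outcome = OutcomeSpec(
        name="renal_function",
        units="mL/min",
        role="primary",
        benefit_direction=BenefitDirection.INCREASE_IS_BETTER,
        rule=ClassificationRule(method="delta_zero"),
        label="RF",
    )
    return GeneratorSpec(
        arm_sizes={"Intervention": 20},
        outcomes=[
            OutcomeGenSpec(
                outcome=outcome,
                targets={"Intervention": MomentTargets(97.1, 2.1, 98.9, 3.7)},
                mix={"Intervention": ResponderMix(12, 5, 3)},
            )
        ],
        seed=seed,
        id_prefix={"Intervention": "S"},
    )


def fixture_f5(seed: int = 5) -> StudyDataset:
    return generate_study(fixture_spec_f5(seed))


def fixture_spec_f2(seed: int = 2) -> GeneratorSpec:
    """Two-arm, four-outcome hypertension-flavoured study (40 + 40 subjects).

    Blood pressure (primary, 3 mmHg risk threshold) responds in most
    Experimental subjects and few Control subjects; the secondary mixes are
    illustrative choices showing heterogeneity in the Experimental arm.
    """
    bp = OutcomeGenSpec(
        outcome=OutcomeSpec(
            name="blood_pressure", units="mmHg", role="primary",
            benefit_direction=BenefitDirection.DECREASE_IS_BETTER,
            rule=ClassificationRule(method="risk_threshold", threshold=3.0),
            label="BP",
        ),
        targets={
            "Control": MomentTargets(139.0, 3.0, 137.0, 2.0, decimals=0),
            "Experimental": MomentTargets(139.0, 2.0, 134.0, 2.0, decimals=0),
        },
        mix={
            "Control": ResponderMix(8, 28, 4),
            "Experimental": ResponderMix(30, 8, 2),
        },
    )
    hrv = OutcomeGenSpec(
        outcome=OutcomeSpec(
            name="heart_rate_variability", units="ms", role="secondary",
            benefit_direction=BenefitDirection.INCREASE_IS_BETTER,
            rule=ClassificationRule(method="mdd", sem=2.0, confidence=0.95),
            label="HRV",
        ),
        targets={
            "Control": MomentTargets(24.0, 3.5, 24.9, 4.2),
            "Experimental": MomentTargets(23.4, 4.0, 24.7, 3.4),
        },
        mix={
            "Control": ResponderMix(6, 32, 2),
            "Experimental": ResponderMix(8, 30, 2),
        },
    )
    stiffness = OutcomeGenSpec(
        outcome=OutcomeSpec(
            name="arterial_stiffness", units="m/s", role="secondary",
            benefit_direction=BenefitDirection.DECREASE_IS_BETTER,
            rule=ClassificationRule(method="risk_threshold", threshold=1.0),
            label="PWV",
        ),
        targets={
            "Control": MomentTargets(9.0, 0.6, 7.9, 0.7),
            "Experimental": MomentTargets(8.9, 0.6, 7.8, 0.6),
        },
        mix={
            "Control": ResponderMix(25, 13, 2),
            "Experimental": ResponderMix(26, 12, 2),
        },
    )
    fmd = OutcomeGenSpec(
        outcome=OutcomeSpec(
            name="endothelial_function", units="%", role="secondary",
            benefit_direction=BenefitDirection.INCREASE_IS_BETTER,
            rule=ClassificationRule(method="risk_threshold", threshold=1.0),
            label="EF",
        ),
        targets={
            "Control": MomentTargets(12.2, 1.5, 11.9, 1.5),
            "Experimental": MomentTargets(12.1, 1.4, 12.0, 1.4),
        },
        mix={
            "Control": ResponderMix(4, 31, 5),
            "Experimental": ResponderMix(5, 30, 5),
        },
    )
    return GeneratorSpec(
        arm_sizes={"Control": 40, "Experimental": 40},
        outcomes=[bp, hrv, stiffness, fmd],
        seed=seed,
        id_prefix={"Control": "C", "Experimental": "E"},
    )


def fixture_f2(seed: int = 2) -> StudyDataset:
    return generate_study(fixture_spec_f2(seed))


def fixture_spec_f4(seed: int = 4) -> GeneratorSpec:
    """'Statistically significant but not clinically meaningful' contrast.

    Cerebral blood flow shifts by ~2.3 mL/min in the Control arm — enough
    for p < 0.001 under tiny SDs, but below the 5 mL/min clinical threshold,
    so every subject stays yellow on the primary; only the cognitive score
    turns some subjects green.  No subject worsens anywhere.
    """
    cbf = OutcomeGenSpec(
        outcome=OutcomeSpec(
            name="cerebral_blood_flow", units="mL/min", role="primary",
            benefit_direction=BenefitDirection.INCREASE_IS_BETTER,
            rule=ClassificationRule(method="risk_threshold", threshold=5.0),
            label="CBF",
        ),
        targets={
            "Control": MomentTargets(52.0, 0.2, 54.3, 0.2),
            "Experimental": MomentTargets(52.1, 0.2, 52.2, 0.3),
        },
        mix={
            "Control": ResponderMix(0, 40, 0),
            "Experimental": ResponderMix(0, 40, 0),
        },
    )
    cognitive = OutcomeGenSpec(
        outcome=OutcomeSpec(
            name="cognitive", units="score", role="secondary",
            benefit_direction=BenefitDirection.INCREASE_IS_BETTER,
            rule=ClassificationRule(method="risk_threshold", threshold=2.0),
            label="COG",
        ),
        targets={
            "Control": MomentTargets(18.8, 0.6, 20.3, 0.7),
            "Experimental": MomentTargets(19.1, 0.6, 20.2, 0.8),
        },
        mix={
            "Control": ResponderMix(10, 30, 0),
            "Experimental": ResponderMix(6, 34, 0),
        },
    )
    return GeneratorSpec(
        arm_sizes={"Control": 40, "Experimental": 40},
        outcomes=[cbf, cognitive],
        seed=seed,
        id_prefix={"Control": "C", "Experimental": "E"},
    )


def fixture_f4(seed: int = 4) -> StudyDataset:
    return generate_study(fixture_spec_f4(seed))


def example_single_subject() -> StudyDataset:
    """One subject, four outcomes: the minimal glyph-cluster walk-through.

    Improved blood pressure, worsened heart rate variability, unchanged
    arterial stiffness, and endothelial function never collected (gray).
    """
    outcomes = [
        OutcomeSpec(
            name="blood_pressure", units="mmHg", role="primary",
            benefit_direction=BenefitDirection.DECREASE_IS_BETTER,
            rule=ClassificationRule(method="risk_threshold", threshold=3.0),
            label="BP",
        ),
        OutcomeSpec(
            name="heart_rate_variability", units="ms", role="secondary",
            benefit_direction=BenefitDirection.INCREASE_IS_BETTER,
            rule=ClassificationRule(method="mdd", sem=2.0, confidence=0.95),
            label="HRV",
        ),
        OutcomeSpec(
            name="arterial_stiffness", units="m/s", role="secondary",
            benefit_direction=BenefitDirection.DECREASE_IS_BETTER,
            rule=ClassificationRule(method="risk_threshold", threshold=1.0),
            label="PWV",
        ),
        OutcomeSpec(
            name="endothelial_function", units="%", role="secondary",
            benefit_direction=BenefitDirection.INCREASE_IS_BETTER,
            rule=ClassificationRule(method="risk_threshold", threshold=1.0),
            label="EF",
        ),
    ]
    subject = SubjectRecord(
        subject_id="S01",
        arm="Experimental",
        values={
            "blood_pressure": (139.0, 134.0),
            "heart_rate_variability": (24.0, 17.5),
            "arterial_stiffness": (9.0, 8.6),
            "endothelial_function": (math.nan, math.nan),
        },
    )
    return StudyDataset(
        outcomes=outcomes, subjects=[subject], arm_labels=["Experimental"]
    )
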