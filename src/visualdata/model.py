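"""Domain types and file I/O for two-timepoint trial datasets.

A study is a wide CSV (one row per subject, ``<outcome>_pre`` /
``<outcome>_post`` column pairs) plus a rules config (YAML or JSON) that
names each outcome's role, benefit direction and classification rule.
Missing measurements are empty cells or the literal ``NA``
(case-insensitive); anything else non-numeric is a format error, never
silently coerced.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "VisualDataError",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "ConstraintError",
    "ResponseStatus",
    "BenefitDirection",
    "ClassificationRule",
    "OutcomeSpec",
    "SubjectRecord",
    "StudyDataset",
    "ClassifiedStudy",
    "is_missing",
    "read_config",
    "write_config",
    "read_study_csv",
    "write_study_csv",
    "write_classified_csv",
    "read_classified_csv",
]


class VisualDataError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(VisualDataError):
    """A file does not conform to the expected layout."""


class ValidationError(VisualDataError):
    """Input data violates a documented contract."""


class ConfigError(VisualDataError):
    """A rules config is incomplete or inconsistent."""


class ConstraintError(VisualDataError):
    """A synthetic-data request cannot be satisfied."""


def is_missing(x: float | None) -> bool:
    """True for the package's missing-value encodings (None or NaN)."""
    return x is None or (isinstance(x, float) and math.isnan(x))


class ResponseStatus(str, enum.Enum):
    """Four-level individual response classification.

    The canonical colour mapping (used by the renderer's default style) is
    IMPROVED -> green, NO_CHANGE -> yellow, WORSENED -> red, MISSING -> gray.
    """

    IMPROVED = "IMPROVED"
    NO_CHANGE = "NO_CHANGE"
    WORSENED = "WORSENED"
    MISSING = "MISSING"

    def __str__(self) -> str:  # serialize as the bare name
        return self.value


class BenefitDirection(str, enum.Enum):
    """Whether an increase or a decrease of the outcome is clinical benefit."""

    INCREASE_IS_BETTER = "increase_is_better"
    DECREASE_IS_BETTER = "decrease_is_better"

    @property
    def sign(self) -> int:
        """+1 if larger values are better, -1 if smaller values are better."""
        return 1 if self is BenefitDirection.INCREASE_IS_BETTER else -1


_METHODS = ("delta_zero", "risk_threshold", "quantile", "mdd")


@dataclass(frozen=True)
class ClassificationRule:
    """One cut-off rule: how a pre/post delta becomes a response status.

    method
        ``delta_zero``      any non-zero delta is a response;
        ``risk_threshold``  |delta| >= threshold is a response;
        ``quantile``        extreme tertile/quartile of the arm's deltas;
        ``mdd``             risk threshold set to the minimal detectable
                            difference z * sqrt(2) * SEM.
    Parameters not used by the chosen method must be absent.
    """

    method: str
    threshold: float | None = None
    k: int | None = None
    sem: float | None = None
    sd_baseline: float | None = None
    icc: float | None = None
    confidence: float | None = None
    quantile_scope: str = "arm"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ConfigError(
                f"unknown classification method {self.method!r}; "
                f"expected one of {_METHODS}"
            )
        given = {
            name
            for name in ("threshold", "k", "sem", "sd_baseline", "icc", "confidence")
            if getattr(self, name) is not None
        }
        allowed = {
            "delta_zero": set(),
            "risk_threshold": {"threshold"},
            "quantile": {"k"},
            "mdd": {"sem", "sd_baseline", "icc", "confidence"},
        }[self.method]
        extra = given - allowed
        if extra:
            raise ConfigError(
                f"rule {self.method!r} does not take parameter(s) {sorted(extra)}"
            )
        if self.method == "risk_threshold":
            if self.threshold is None:
                raise ConfigError("risk_threshold rule requires 'threshold'")
            if not self.threshold > 0:
                raise ConfigError(
                    f"risk threshold must be > 0, got {self.threshold}"
                )
        elif self.method == "quantile":
            if self.k not in (3, 4):
                raise ConfigError(f"quantile rule requires k in {{3, 4}}, got {self.k}")
            if self.quantile_scope not in ("arm", "study"):
                raise ConfigError(
                    f"quantile_scope must be 'arm' or 'study', got {self.quantile_scope!r}"
                )
        elif self.method == "mdd":
            conf = self.confidence if self.confidence is not None else 0.95
            if not 0 < conf < 1:
                raise ConfigError(f"confidence must lie in (0, 1), got {conf}")
            object.__setattr__(self, "confidence", conf)
            if self.sem is not None:
                if not self.sem > 0:
                    raise ConfigError(f"sem must be > 0, got {self.sem}")
                if self.sd_baseline is not None or self.icc is not None:
                    raise ConfigError("give either 'sem' or ('sd_baseline', 'icc'), not both")
            else:
                if self.sd_baseline is None or self.icc is None:
                    raise ConfigError(
                        "mdd rule requires 'sem' or both 'sd_baseline' and 'icc'"
                    )
                if not self.sd_baseline > 0:
                    raise ConfigError(f"sd_baseline must be > 0, got {self.sd_baseline}")
                if not 0 <= self.icc < 1:
                    raise ConfigError(f"icc must lie in [0, 1), got {self.icc}")

    @property
    def effective_sem(self) -> float:
        """SEM for an mdd rule: given directly or sd_baseline * sqrt(1 - ICC)."""
        if self.method != "mdd":
            raise ConfigError("effective_sem is defined for mdd rules only")
        if self.sem is not None:
            return self.sem
        return self.sd_baseline * math.sqrt(1.0 - self.icc)

    def to_dict(self) -> dict:
        out: dict = {"method": self.method}
        for name in ("threshold", "k", "sem", "sd_baseline", "icc", "confidence"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        if self.method == "quantile" and self.quantile_scope != "arm":
            out["quantile_scope"] = self.quantile_scope
        return out


@dataclass(frozen=True)
class OutcomeSpec:
    """One measured variable: identity, units, role and classification rule."""

    name: str
    units: str
    role: str  # "primary" | "secondary"
    benefit_direction: BenefitDirection
    rule: ClassificationRule
    label: str | None = None  # optional 1-3 character glyph label

    def __post_init__(self) -> None:
        if self.role not in ("primary", "secondary"):
            raise ConfigError(
                f"outcome {self.name!r}: role must be 'primary' or 'secondary', "
                f"got {self.role!r}"
            )
        if not isinstance(self.benefit_direction, BenefitDirection):
            object.__setattr__(
                self, "benefit_direction", BenefitDirection(self.benefit_direction)
            )
        if self.label is not None and not 1 <= len(self.label) <= 3:
            raise ConfigError(f"outcome {self.name!r}: label must be 1-3 characters")


@dataclass
class SubjectRecord:
    """One participant: id, arm, and a (pre, post) pair per outcome.

    Either member of a pair may be NaN (missing). ``values`` must carry an
    entry for every outcome of the study the record belongs to.
    """

    subject_id: str
    arm: str
    values: dict[str, tuple[float, float]]

    def pair(self, outcome: str) -> tuple[float, float]:
        try:
            return self.values[outcome]
        except KeyError:
            raise ValidationError(
                f"subject {self.subject_id!r} has no values for outcome {outcome!r}"
            ) from None


@dataclass
class StudyDataset:
    """A whole two-arm (or single-arm), two-timepoint study."""

    outcomes: list[OutcomeSpec]
    subjects: list[SubjectRecord]
    arm_labels: list[str]

    def __post_init__(self) -> None:
        primaries = [o for o in self.outcomes if o.role == "primary"]
        if len(primaries) != 1:
            raise ConfigError(
                f"exactly one outcome must have role 'primary'; got {len(primaries)}"
            )
        names = [o.name for o in self.outcomes]
        if len(set(names)) != len(names):
            raise ConfigError("outcome names must be unique")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject_id values: {dupes}")
        if len(set(self.arm_labels)) != len(self.arm_labels):
            raise ValidationError("arm_labels must be unique")
        for s in self.subjects:
            if s.arm not in self.arm_labels:
                raise ValidationError(
                    f"subject {s.subject_id!r} has arm {s.arm!r} not in arm_labels "
                    f"{self.arm_labels}"
                )
            for o in self.outcomes:
                if o.name not in s.values:
                    raise ValidationError(
                        f"subject {s.subject_id!r} lacks a value entry for "
                        f"outcome {o.name!r}"
                    )

    @property
    def primary_outcome(self) -> OutcomeSpec:
        return next(o for o in self.outcomes if o.role == "primary")

    @property
    def outcome_names(self) -> list[str]:
        return [o.name for o in self.outcomes]

    def outcome(self, name: str) -> OutcomeSpec:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise ValidationError(f"unknown outcome {name!r}")

    def subjects_in_arm(self, arm: str) -> list[SubjectRecord]:
        if arm not in self.arm_labels:
            raise ValidationError(f"unknown arm {arm!r}")
        return [s for s in self.subjects if s.arm == arm]


@dataclass
class ClassifiedStudy:
    """Status for every (subject, outcome) cell of a study.

    ``statuses`` is total: a cell is MISSING iff its pre or post value is
    missing; every other cell carries the rule's verdict.
    """

    statuses: dict[tuple[str, str], ResponseStatus]
    source: StudyDataset

    def __post_init__(self) -> None:
        expected = {
            (s.subject_id, o.name)
            for s in self.source.subjects
            for o in self.source.outcomes
        }
        if set(self.statuses) != expected:
            raise ValidationError(
                "status matrix is not total over subjects x outcomes"
            )

    def status(self, subject_id: str, outcome: str) -> ResponseStatus:
        return self.statuses[(subject_id, outcome)]

    def subject_statuses(self, subject_id: str) -> list[ResponseStatus]:
        """Statuses in config outcome order, primary first."""
        ordered = sorted(self.source.outcomes, key=lambda o: o.role != "primary")
        return [self.statuses[(subject_id, o.name)] for o in ordered]


# ---------------------------------------------------------------------------
# Config I/O


def _rule_from_dict(d: Mapping, outcome: str) -> ClassificationRule:
    if "method" not in d:
        raise ConfigError(f"outcome {outcome!r}: rule needs a 'method' key")
    known = {
        "method", "threshold", "k", "sem", "sd_baseline", "icc",
        "confidence", "quantile_scope",
    }
    unknown = set(d) - known
    if unknown:
        raise ConfigError(
            f"outcome {outcome!r}: unknown rule key(s) {sorted(unknown)}"
        )
    kwargs = {k: v for k, v in d.items() if k != "quantile_scope"}
    try:
        return ClassificationRule(
            quantile_scope=d.get("quantile_scope", "arm"), **kwargs
        )
    except ConfigError as exc:
        raise ConfigError(f"outcome {outcome!r}: {exc}") from None


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def read_config(path: str | Path) -> dict:
    """Parse a rules config (YAML or JSON by extension).

    Returns ``{"outcomes": [OutcomeSpec...], "arms": [...] | None,
    "style": dict}``.  Exactly one outcome must be primary and every outcome
    must state its benefit direction; both are checked here, not deferred.
    """
    data = _load_mapping(path)
    if "outcomes" not in data or not isinstance(data["outcomes"], list):
        raise ConfigError(f"{path}: config needs an 'outcomes' list")
    outcomes = []
    for entry in data["outcomes"]:
        if not isinstance(entry, dict):
            raise ConfigError(f"{path}: each outcome must be a mapping")
        missing_keys = {"name", "role", "benefit_direction", "rule"} - set(entry)
        if missing_keys:
            raise ConfigError(
                f"{path}: outcome entry missing key(s) {sorted(missing_keys)}"
            )
        try:
            direction = BenefitDirection(entry["benefit_direction"])
        except ValueError:
            raise ConfigError(
                f"outcome {entry['name']!r}: benefit_direction must be "
                f"'increase_is_better' or 'decrease_is_better', got "
                f"{entry['benefit_direction']!r}"
            ) from None
        outcomes.append(
            OutcomeSpec(
                name=str(entry["name"]),
                units=str(entry.get("units", "")),
                role=entry["role"],
                benefit_direction=direction,
                rule=_rule_from_dict(entry["rule"], entry["name"]),
                label=entry.get("label"),
            )
        )
    primaries = [o for o in outcomes if o.role == "primary"]
    if len(primaries) != 1:
        raise ConfigError(
            f"{path}: exactly one outcome must be primary, found {len(primaries)}"
        )
    arms = data.get("arms")
    if arms is not None:
        arms = [str(a) for a in arms]
    return {"outcomes": outcomes, "arms": arms, "style": data.get("style", {})}


def write_config(
    outcomes: Sequence[OutcomeSpec],
    path: str | Path,
    arms: Sequence[str] | None = None,
    style: Mapping | None = None,
) -> None:
    """Write a rules config as YAML (or JSON if the path ends in .json)."""
    data: dict = {
        "outcomes": [
            {
                "name": o.name,
                "units": o.units,
                "role": o.role,
                "benefit_direction": o.benefit_direction.value,
                **({"label": o.label} if o.label else {}),
                "rule": o.rule.to_dict(),
            }
            for o in outcomes
        ]
    }
    if arms is not None:
        data["arms"] = list(arms)
    if style:
        data["style"] = dict(style)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Study CSV I/O (wide format)

_MISSING_TOKENS = {"", "na"}


def _parse_cell(raw: str, column: str, subject: str) -> float:
    token = raw.strip()
    if token.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"subject {subject!r}, column {column!r}: cannot parse {raw!r} as a "
            "number (missing values are empty cells or 'NA')"
        ) from None


def read_study_csv(path: str | Path, config: str | Path) -> StudyDataset:
    """Read a wide study CSV against a rules config.

    The CSV needs ``subject_id``, ``arm`` and one ``<name>_pre`` /
    ``<name>_post`` pair per configured outcome; column order is irrelevant
    and blank or ``NA`` cells become missing values.
    """
    cfg = read_config(config)
    outcomes: list[OutcomeSpec] = cfg["outcomes"]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    required = ["subject_id", "arm"]
    for o in outcomes:
        required += [f"{o.name}_pre", f"{o.name}_post"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    subjects = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"]).strip()
        if not sid:
            raise FormatError(f"{path}: blank subject_id")
        values = {}
        for o in outcomes:
            pre = _parse_cell(row[f"{o.name}_pre"], f"{o.name}_pre", sid)
            post = _parse_cell(row[f"{o.name}_post"], f"{o.name}_post", sid)
            values[o.name] = (pre, post)
        subjects.append(
            SubjectRecord(subject_id=sid, arm=str(row["arm"]).strip(), values=values)
        )

    seen_arms = list(dict.fromkeys(s.arm for s in subjects))
    arms = cfg["arms"] if cfg["arms"] is not None else seen_arms
    extra = [a for a in seen_arms if a not in arms]
    if extra:
        raise ValidationError(
            f"{path}: arm label(s) {extra} not listed in the config's 'arms'"
        )
    return StudyDataset(outcomes=outcomes, subjects=subjects, arm_labels=arms)


def write_study_csv(study: StudyDataset, path: str | Path) -> None:
    """Write a StudyDataset back to the wide CSV layout (NaN -> empty cell)."""
    cols: dict[str, list] = {
        "subject_id": [s.subject_id for s in study.subjects],
        "arm": [s.arm for s in study.subjects],
    }
    for o in study.outcomes:
        cols[f"{o.name}_pre"] = [s.values[o.name][0] for s in study.subjects]
        cols[f"{o.name}_post"] = [s.values[o.name][1] for s in study.subjects]
    pd.DataFrame(cols).to_csv(path, index=False, na_rep="")


def write_classified_csv(classified: ClassifiedStudy, path: str | Path) -> None:
    """One row per subject; one status column per outcome, plus id and arm."""
    study = classified.source
    cols: dict[str, list] = {
        "subject_id": [s.subject_id for s in study.subjects],
        "arm": [s.arm for s in study.subjects],
    }
    for o in study.outcomes:
        cols[o.name] = [
            classified.statuses[(s.subject_id, o.name)].value for s in study.subjects
        ]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_classified_csv(path: str | Path, config: str | Path) -> ClassifiedStudy:
    """Read a status matrix written by :func:`write_classified_csv`.

    The returned ClassifiedStudy carries a skeleton StudyDataset (statuses
    only; all measurement values NaN) sufficient for rendering and counting.
    """
    cfg = read_config(config)
    outcomes: list[OutcomeSpec] = cfg["outcomes"]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ["subject_id", "arm"] + [o.name for o in outcomes]:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    subjects = []
    statuses: dict[tuple[str, str], ResponseStatus] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"]).strip()
        values = {o.name: (math.nan, math.nan) for o in outcomes}
        subjects.append(
            SubjectRecord(subject_id=sid, arm=str(row["arm"]).strip(), values=values)
        )
        for o in outcomes:
            token = str(row[o.name]).strip().upper()
            try:
                statuses[(sid, o.name)] = ResponseStatus(token)
            except ValueError:
                raise FormatError(
                    f"{path}: subject {sid!r}, outcome {o.name!r}: "
                    f"{row[o.name]!r} is not a response status"
                ) from None
    seen_arms = list(dict.fromkeys(s.arm for s in subjects))
    arms = cfg["arms"] if cfg["arms"] is not None else seen_arms
    study = StudyDataset(outcomes=outcomes, subjects=subjects, arm_labels=arms)
    return ClassifiedStudy(statuses=statuses, source=study)
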