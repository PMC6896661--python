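"""Glyph chart: one cluster per subject, coloured circles per outcome.

Each subject is drawn as one large circle (the primary outcome) with the
secondary outcomes as smaller circles on an arc below it, every circle
filled with the colour of its response status (green improved, yellow no
change, red worsened, gray missing).  Arms become separate panels, so a
whole two-arm study reads as two grids of clusters.

Output is standalone SVG 1.1.  Every status circle carries
``data-subject`` / ``data-outcome`` / ``data-status`` attributes, which
makes the chart machine-readable: the full status matrix can be recovered
from the file.  Rendering is deterministic — no timestamps, no generated
ids — so identical inputs give byte-identical documents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence
from xml.etree import ElementTree
from xml.sax.saxutils import escape, quoteattr

from .model import (
    ClassifiedStudy,
    ConfigError,
    ResponseStatus,
    ValidationError,
    VisualDataError,
)

__all__ = [
    "GlyphStyle",
    "Circle",
    "SubjectCluster",
    "PanelLayout",
    "GlyphLayout",
    "layout_subject",
    "layout_study",
    "render_svg",
    "render_svg_string",
    "render_png",
    "parse_status_matrix",
]

_STATUS_ORDER = (
    ResponseStatus.IMPROVED,
    ResponseStatus.NO_CHANGE,
    ResponseStatus.WORSENED,
    ResponseStatus.MISSING,
)

_LEGEND_TEXT = {
    ResponseStatus.IMPROVED: "Improved",
    ResponseStatus.NO_CHANGE: "No change",
    ResponseStatus.WORSENED: "Worsened",
    ResponseStatus.MISSING: "Missing",
}


@dataclass(frozen=True)
class GlyphStyle:
    """Colours and geometry of the glyphs.

    The default palette is a colourblind-checked green/yellow/red/gray;
    ``secondary_radius_ratio`` keeps secondary circles visibly smaller than
    the primary.  ``label_mode='text'`` prints a 1-3 character outcome label
    inside each circle in place of pictogram artwork.
    """

    color_improved: str = "#1E8F4E"
    color_no_change: str = "#F2C200"
    color_worsened: str = "#D7301F"
    color_missing: str = "#BDBDBD"
    primary_radius: float = 12.0
    secondary_radius_ratio: float = 0.45
    label_mode: str = "none"  # "none" | "text"

    def __post_init__(self) -> None:
        colors = [
            self.color_improved,
            self.color_no_change,
            self.color_worsened,
            self.color_missing,
        ]
        if len({c.lower() for c in colors}) != 4:
            raise ConfigError("the four status colours must be pairwise distinct")
        if not 0 < self.secondary_radius_ratio < 1:
            raise ConfigError(
                "secondary_radius_ratio must lie in (0, 1), got "
                f"{self.secondary_radius_ratio}"
            )
        if self.primary_radius <= 0:
            raise ConfigError(f"primary_radius must be > 0, got {self.primary_radius}")
        if self.label_mode not in ("none", "text"):
            raise ConfigError(f"label_mode must be 'none' or 'text', got {self.label_mode!r}")

    def color_for(self, status: ResponseStatus) -> str:
        return {
            ResponseStatus.IMPROVED: self.color_improved,
            ResponseStatus.NO_CHANGE: self.color_no_change,
            ResponseStatus.WORSENED: self.color_worsened,
            ResponseStatus.MISSING: self.color_missing,
        }[status]

    @classmethod
    def from_dict(cls, d: dict) -> "GlyphStyle":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown style key(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class Circle:
    """One positioned, coloured status circle (absolute SVG coordinates)."""

    cx: float
    cy: float
    r: float
    status: ResponseStatus
    subject_id: str
    outcome: str
    is_primary: bool
    label: str | None = None


@dataclass(frozen=True)
class SubjectCluster:
    subject_id: str
    origin: tuple[float, float]  # primary-circle centre
    circles: tuple[Circle, ...]


@dataclass(frozen=True)
class PanelLayout:
    arm: str
    origin: tuple[float, float]
    title_pos: tuple[float, float]
    width: float
    height: float
    clusters: tuple[SubjectCluster, ...]


@dataclass(frozen=True)
class GlyphLayout:
    width: float
    height: float
    panels: tuple[PanelLayout, ...]

    @property
    def circles(self) -> list[Circle]:
        return [c for p in self.panels for cl in p.clusters for c in cl.circles]


_GAP_RATIO = 0.25  # clearance between circles, as a fraction of the small radius


def _secondary_positions(m: int, style: GlyphStyle) -> list[tuple[float, float]]:
    """Relative centres for m secondary circles on a 180-degree arc below."""
    r_s = style.primary_radius * style.secondary_radius_ratio
    gap = _GAP_RATIO * r_s
    base = style.primary_radius + r_s + gap
    if m == 1:
        return [(0.0, base)]
    dtheta = math.pi / (m + 1)
    # adjacent secondaries must clear each other: chord >= 2 r_s + gap
    needed = (2 * r_s + gap) / (2 * math.sin(dtheta / 2))
    ring = max(base, needed)
    out = []
    for i in range(m):
        theta = dtheta * (i + 1)
        out.append((-ring * math.cos(theta), ring * math.sin(theta)))
    return out


def layout_subject(
    statuses: Sequence[ResponseStatus],
    style: GlyphStyle,
    subject_id: str = "",
    outcome_names: Sequence[str] | None = None,
    labels: Sequence[str | None] | None = None,
) -> tuple[Circle, ...]:
    """Geometry for one subject: primary circle at (0, 0), secondaries below.

    ``statuses`` is ordered primary first.  Secondary circles sit at equal
    angular spacing on an arc under the primary, far enough out that no two
    circles of the cluster overlap regardless of their count.
    """
    if len(statuses) == 0:
        raise ValidationError("layout_subject needs at least the primary status")
    if outcome_names is None:
        outcome_names = [f"outcome_{i}" for i in range(len(statuses))]
    if labels is None:
        labels = [None] * len(statuses)
    r_s = style.primary_radius * style.secondary_radius_ratio
    circles = [
        Circle(
            cx=0.0,
            cy=0.0,
            r=style.primary_radius,
            status=statuses[0],
            subject_id=subject_id,
            outcome=outcome_names[0],
            is_primary=True,
            label=labels[0],
        )
    ]
    for (dx, dy), status, name, label in zip(
        _secondary_positions(len(statuses) - 1, style),
        statuses[1:],
        outcome_names[1:],
        labels[1:],
    ):
        circles.append(
            Circle(
                cx=dx, cy=dy, r=r_s, status=status, subject_id=subject_id,
                outcome=name, is_primary=False, label=label,
            )
        )
    return tuple(circles)


def _cluster_extent(n_secondary: int, style: GlyphStyle) -> tuple[float, float, float]:
    """(half_width, up, down) extents of a cluster around the primary centre."""
    r_p = style.primary_radius
    r_s = r_p * style.secondary_radius_ratio
    half_w, down = r_p, r_p
    for dx, dy in _secondary_positions(n_secondary, style):
        half_w = max(half_w, abs(dx) + r_s)
        down = max(down, dy + r_s)
    return half_w, r_p, down


_PANEL_PAD = 16.0
_TITLE_H = 22.0
_LEGEND_H = 36.0


def layout_study(
    classified: ClassifiedStudy,
    style: GlyphStyle | None = None,
    columns_per_panel: int = 8,
    sort_by: str = "id",
) -> GlyphLayout:
    """Position every subject cluster into one panel per arm.

    Panels are stacked top-to-bottom in ``arm_labels`` order; within a panel
    clusters flow left-to-right, top-to-bottom, sorted by subject id (or by
    primary-outcome status, then id, with ``sort_by='status'``).  The layout
    is a pure function of its inputs.
    """
    if style is None:
        style = GlyphStyle()
    if columns_per_panel < 1:
        raise ValidationError(f"columns_per_panel must be >= 1, got {columns_per_panel}")
    if sort_by not in ("id", "status"):
        raise ValidationError(f"sort_by must be 'id' or 'status', got {sort_by!r}")
    study = classified.source
    ordered_outcomes = sorted(study.outcomes, key=lambda o: o.role != "primary")
    names = [o.name for o in ordered_outcomes]
    labels = [o.label for o in ordered_outcomes]
    n_secondary = len(names) - 1
    half_w, up, down = _cluster_extent(n_secondary, style)
    cell_w = 2 * half_w + 10.0
    cell_h = up + down + 10.0

    panels = []
    y_cursor = _PANEL_PAD
    max_panel_w = 0.0
    for arm in study.arm_labels:
        members = study.subjects_in_arm(arm)
        if sort_by == "status":
            rank = {st: i for i, st in enumerate(_STATUS_ORDER)}
            members = sorted(
                members,
                key=lambda s: (
                    rank[classified.statuses[(s.subject_id, names[0])]],
                    s.subject_id,
                ),
            )
        else:
            members = sorted(members, key=lambda s: s.subject_id)
        n_rows = math.ceil(len(members) / columns_per_panel) if members else 0
        panel_w = columns_per_panel * cell_w + 2 * _PANEL_PAD
        panel_h = _TITLE_H + n_rows * cell_h + _PANEL_PAD
        origin = (_PANEL_PAD, y_cursor)
        clusters = []
        for idx, s in enumerate(members):
            row, col = divmod(idx, columns_per_panel)
            cx = origin[0] + _PANEL_PAD + col * cell_w + cell_w / 2
            cy = origin[1] + _TITLE_H + row * cell_h + up + 5.0
            statuses = [classified.statuses[(s.subject_id, nm)] for nm in names]
            rel = layout_subject(statuses, style, s.subject_id, names, labels)
            abs_circles = tuple(
                Circle(
                    cx=c.cx + cx, cy=c.cy + cy, r=c.r, status=c.status,
                    subject_id=c.subject_id, outcome=c.outcome,
                    is_primary=c.is_primary, label=c.label,
                )
                for c in rel
            )
            clusters.append(
                SubjectCluster(subject_id=s.subject_id, origin=(cx, cy),
                               circles=abs_circles)
            )
        panels.append(
            PanelLayout(
                arm=arm,
                origin=origin,
                title_pos=(origin[0] + _PANEL_PAD, origin[1] + _TITLE_H - 8.0),
                width=panel_w,
                height=panel_h,
                clusters=tuple(clusters),
            )
        )
        max_panel_w = max(max_panel_w, panel_w)
        y_cursor += panel_h + _PANEL_PAD
    width = max_panel_w + 2 * _PANEL_PAD
    height = y_cursor + _LEGEND_H
    return GlyphLayout(width=width, height=height, panels=tuple(panels))


def _fmt(v: float) -> str:
    s = f"{v:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def render_svg_string(layout: GlyphLayout, style: GlyphStyle | None = None) -> str:
    """Serialize a layout to a standalone SVG 1.1 document (deterministic)."""
    if style is None:
        style = GlyphStyle()
    w, h = _fmt(layout.width), _fmt(layout.height)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w}" height="{h}" viewBox="0 0 {w} {h}">',
        f'<rect x="0" y="0" width="{w}" height="{h}" fill="#FFFFFF"/>',
    ]
    for panel in layout.panels:
        lines.append(
            f'<g class="panel" data-arm={quoteattr(panel.arm)}>'
        )
        tx, ty = panel.title_pos
        lines.append(
            f'<text x="{_fmt(tx)}" y="{_fmt(ty)}" font-family="sans-serif" '
            f'font-size="14" font-weight="bold">{escape(panel.arm)}</text>'
        )
        for cluster in panel.clusters:
            lines.append(f'<g class="subject" data-subject={quoteattr(cluster.subject_id)}>')
            for c in cluster.circles:
                lines.append(
                    f'<circle cx="{_fmt(c.cx)}" cy="{_fmt(c.cy)}" r="{_fmt(c.r)}" '
                    f'fill="{style.color_for(c.status)}" stroke="#444444" '
                    f'stroke-width="0.5" '
                    f'data-subject={quoteattr(c.subject_id)} '
                    f'data-outcome={quoteattr(c.outcome)} '
                    f'data-status="{c.status.value}"/>'
                )
                if style.label_mode == "text" and c.label:
                    fs = _fmt(c.r * 0.9)
                    lines.append(
                        f'<text x="{_fmt(c.cx)}" y="{_fmt(c.cy)}" text-anchor="middle" '
                        f'dominant-baseline="central" font-family="sans-serif" '
                        f'font-size="{fs}">{escape(c.label)}</text>'
                    )
            lines.append("</g>")
        lines.append("</g>")
    # legend: plain swatches, no data-status so they never count as glyphs
    ly = layout.height - _LEGEND_H / 2
    lx = _PANEL_PAD
    lines.append('<g class="legend">')
    for status in _STATUS_ORDER:
        lines.append(
            f'<circle cx="{_fmt(lx + 6)}" cy="{_fmt(ly)}" r="6" '
            f'fill="{style.color_for(status)}" stroke="#444444" stroke-width="0.5"/>'
        )
        text = _LEGEND_TEXT[status]
        lines.append(
            f'<text x="{_fmt(lx + 16)}" y="{_fmt(ly + 4)}" font-family="sans-serif" '
            f'font-size="12">{escape(text)}</text>'
        )
        lx += 16 + 7.5 * len(text) + 18
    lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def render_svg(layout: GlyphLayout, style: GlyphStyle | None, path: str | Path) -> None:
    """Write the chart to ``path`` as UTF-8 SVG."""
    text = render_svg_string(layout, style)
    try:
        Path(path).write_text(text, encoding="utf-8", newline="\n")
    except OSError as exc:
        raise VisualDataError(f"cannot write SVG to {path}: {exc}") from exc


def render_png(
    layout: GlyphLayout,
    style: GlyphStyle | None,
    path: str | Path,
    backend: Callable[[str, str], None] | None = None,
) -> None:
    """Rasterize through a pluggable backend ``backend(svg_text, png_path)``.

    No rasterizer is bundled; without a backend this raises.
    """
    if backend is None:
        raise VisualDataError(
            "PNG rasterization needs a backend callable(svg_text, png_path); "
            "none is bundled"
        )
    backend(render_svg_string(layout, style), str(path))


def parse_status_matrix(svg: str | Path) -> dict[tuple[str, str], ResponseStatus]:
    """Recover the status matrix from a rendered chart.

    Reads the ``data-*`` attributes of every status circle, so
    ``parse_status_matrix(render_svg(...))`` inverts rendering exactly.
    Accepts a path or the SVG text itself.
    """
    text = str(svg)
    if not text.lstrip().startswith("<"):
        text = Path(svg).read_text(encoding="utf-8")
    root = ElementTree.fromstring(text)
    ns = "{http://www.w3.org/2000/svg}"
    matrix: dict[tuple[str, str], ResponseStatus] = {}
    for el in root.iter(f"{ns}circle"):
        status = el.get("data-status")
        if status is None:
            continue  # legend swatch
        key = (el.get("data-subject"), el.get("data-outcome"))
        matrix[key] = ResponseStatus(status)
    return matrix
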