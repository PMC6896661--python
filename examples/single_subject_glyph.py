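"""Render the minimal glyph cluster: one subject, four outcomes.

The subject lowered blood pressure past the 3 mmHg cut-off (green primary),
lost heart-rate variability beyond the minimal detectable difference (red),
changed arterial stiffness by less than 1 m/s (yellow), and endothelial
function was never measured (gray).
"""

from visualdata import (
    GlyphStyle,
    classify_study,
    example_single_subject,
    layout_study,
    render_svg,
)

study = example_single_subject()
classified = classify_study(study)

for (sid, outcome), status in sorted(classified.statuses.items()):
    pre, post = study.subjects[0].values[outcome]
    print(f"{outcome:25s} pre={pre:<7g} post={post:<7g} -> {status.value}")

style = GlyphStyle(label_mode="text")
render_svg(layout_study(classified, style), style, "single_subject.svg")
print("\nwrote single_subject.svg — one large circle (primary outcome) with")
print("three small ones below it, coloured green/red/yellow/gray by status.")
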