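"""Demo: the per-subject line chart the glyph chart improves upon.

Draws the conventional individual-data presentation — one line per subject
from pre to post, primary outcome only — next to nothing else, which is the
problem: secondary outcomes need their own figures and response status is
left to the reader's eye.  Untested demo surface; requires matplotlib.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from visualdata import fixture_f5

study = fixture_f5()
fig, ax = plt.subplots(figsize=(4, 5))
for s in study.subjects:
    pre, post = s.values["renal_function"]
    d = post - pre
    color = "#1E8F4E" if d > 0 else ("#D7301F" if d < 0 else "#F2C200")
    ax.plot([0, 1], [pre, post], marker="o", color=color, alpha=0.7, lw=1)
ax.set_xticks([0, 1], ["pre", "post"])
ax.set_ylabel("renal function (mL/min)")
ax.set_title("one line per subject, primary outcome only")
fig.tight_layout()
fig.savefig("means_vs_individuals.png", dpi=150)
print("wrote means_vs_individuals.png — readable for one outcome and 20")
print("subjects, but it does not scale to four outcomes and 80 subjects.")
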