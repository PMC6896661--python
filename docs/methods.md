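# Methods

## Classification model

Every (subject, outcome) cell is classified from the change score
Δ = post − pre and the outcome's benefit direction s (+1 if an increase is
clinical benefit, −1 otherwise). A cell with a missing pre **or** post value
is MISSING and no rule is evaluated; everything else receives exactly one of
IMPROVED / NO_CHANGE / WORSENED. Four rules are implemented:

* **delta_zero** — sΔ > 0 is IMPROVED, sΔ < 0 WORSENED, Δ = 0 (exact, at
  stored precision) NO_CHANGE. The rule knowingly ignores measurement error
  and is implemented as stated rather than softened; use `mdd` when error
  matters.
* **risk_threshold** — |Δ| ≥ t is a change, signed by direction. The
  boundary is **inclusive**: a blood-pressure drop of exactly 3 mmHg counts
  as a response. This tie rule is a package decision, documented and tested,
  so analyses are auditable. A small registry ships the published
  change-score anchors (blood pressure 3 mmHg, arterial stiffness 1 m/s,
  flow-mediated dilation 1%). Resting heart rate's published 75 bpm
  criterion is a *level*, not a change score, so it is deliberately absent
  from the registry; asking for it yields a missing key and the caller must
  supply an explicit threshold.
* **quantile** — the arm's non-missing deltas are split into k ∈ {3, 4}
  equal-probability groups by linear-interpolation sample quantiles; the
  extreme group in the benefit direction is IMPROVED, the opposite extreme
  WORSENED, the middle NO_CHANGE. A delta lying exactly on a cut goes to the
  more central group, so an all-identical sample is entirely NO_CHANGE.
  Quantiles are computed **within arm** by default (`quantile_scope: arm`):
  pooling would let arm imbalance leak into the classification. A `study`
  scope exists for single-arm or pooled analyses.
* **mdd** — a risk threshold set to the minimal detectable difference of a
  change score, z₍(1+c)/2₎·√2·SEM, with confidence c defaulting to 0.95.
  SEM may be given directly or derived from test-retest inputs as
  SD_baseline·√(1 − ICC), the standard reliability formulation. Classifying
  under `mdd` is cell-by-cell identical to `risk_threshold` at the computed
  cut-off (tested).

Per-arm response percentages use the **full arm size** (missing subjects
included) as the denominator — "25% (n=5) of 20 enrolled" — with an
`observed` denominator available but not default.

## Summary table

The conventional contrast is a per-outcome row of mean (SD) for each
(arm, time) cell — sample SD, n−1 — plus a two-way mixed-design ANOVA
(between: arm; within: time) computed directly from sums of squares.
Subjects missing either timepoint are dropped per outcome (listwise
deletion, count logged). Because every retained subject contributes to both
timepoints, the cell frequencies stay proportional and the weighted
decomposition is exact even with unequal arm sizes; for the 2 × 2 design the
effects reduce to identities on subject means and change scores, which the
tests exploit as an independent oracle alongside a permutation oracle and a
cross-check against `pingouin.mixed_anova`. Degenerate inputs (no error
variance) return F = 0, p = 1 for null effects and F = ∞, p = 0 for
non-null ones rather than NaN. p-values below 0.001 *display* as "<0.001";
stored values stay exact. No multiplicity correction is applied across
outcomes: the table mirrors the unadjusted per-outcome convention it
reproduces.

## Glyph chart

One cluster per subject: the primary outcome is a large circle (default
radius 12 SVG units) at the cluster origin, secondaries are smaller circles
(ratio 0.45) at equal angular spacing on a 180° arc below it. The arc radius
grows with the secondary count so that no two circles of a cluster ever
overlap (property-tested up to 8 secondaries and ratios 0.2–0.8). Clusters
flow left-to-right, top-to-bottom in subject-id order (a `sort_by: status`
option groups responders; the default is id order because the chart's
message does not depend on ordering), one panel per arm, panels stacked in
config order, 8 columns per panel by default so a 40-subject panel fits a
printable page. Colours default to a colourblind-checked green/yellow/red/
gray (#1E8F4E, #F2C200, #D7301F, #BDBDBD) and are fully overridable; the
four colours must stay pairwise distinct. Instead of pictogram artwork the
circles can carry 1–3 character text labels (`label_mode: text`), which
preserves the identification function in plain SVG. Output is SVG 1.1 with
`data-subject`/`data-outcome`/`data-status` attributes on every status
circle, making rendering invertible (tested as an exact round-trip) and
byte-deterministic (no timestamps or generated ids). PNG rasterization is a
pluggable hook; no rasterizer is bundled.

## Synthetic studies

The generator exists so that every documented number is reproducible
without any external data. For each arm × outcome it takes printed-precision
targets (pre mean/SD, post mean/SD, `decimals`) and a responder mix under
the outcome's own rule, and constructs values in four steps:

1. **Baselines** are normal draws affinely rescaled to the exact pre
   moments.
2. **Statuses are allocated by baseline rank**: the class whose change
   window points upward gets the lowest baselines and vice versa, with
   missing subjects a uniform random subset. This mimics regression to the
   mean and is also what makes tight printed moments feasible — a subject
   asked to worsen from an already-high baseline would blow up the post-value
   spread.
3. **Post values** start as a draw that regresses on baseline with
   test-retest correlation 0.7 (repeated clinical measures typically
   correlate 0.6–0.8; an uncorrelated draw would inflate change-score
   spread beyond anything a real trial shows), clamped into each subject's
   class window — e.g. Δ ≤ −3 for an improver under a 3 mmHg
   decrease-is-better threshold, Δ = 0 exactly for delta-zero NO_CHANGE.
4. **Moment matching**: the free post values are affinely rescaled so the
   overall post mean/SD hit the targets exactly, accounting for pinned
   values (delta-zero NO_CHANGE and boundary-clipped subjects); any value
   pushed across its class window is clipped to the boundary with a small
   interior jitter and pinned, and the rescale repeats. The loop terminates
   because the pinned set only grows. Afterwards the study is re-classified
   with the real rules and the realized moments are checked against the
   targets at their printed precision; any violation raises a
   `ConstraintError` naming the conflict (e.g. a post SD too small to hold
   the boundary-pinned subjects). Infeasible requests therefore fail loudly
   instead of drifting.

Everything is a pure function of the seed; the responder mix and the rounded
moments are invariant across seeds by construction, which is what the
reproduction script relies on. Quantile rules are refused by the generator:
their counts are fixed by k, not by a requestable mix.

### Packaged studies

* **f5** — 20 subjects, one arm, one outcome (`renal_function`,
  increase-is-better, delta-zero), mix 12/5/3/0, pre 97.1 (2.1), post
  98.9 (3.7). With the default seed the paired t-test gives p = 0.036 — a
  "significant" group improvement despite 8/20 non-improvers.
* **f2** — 40 + 40 subjects (Control, Experimental), four outcomes. Blood
  pressure (primary, 3 mmHg threshold) uses mixes 8/28/4 vs 30/8/2; the
  published table cells (139 (3) → 137 (2) vs 139 (2) → 134 (2) etc.) are
  hit at printed precision for all four outcomes. The secondary mixes are
  illustrative choices (HRV under an mdd rule with SEM 2.0 ms; stiffness
  and endothelial function under 1-unit thresholds) satisfying the
  qualitative pattern: heterogeneous secondary responses in the
  Experimental arm.
* **f4** — 40 + 40 subjects, cerebral blood flow (primary, 5 mL/min
  threshold) and a cognitive score (2-point threshold). The Control arm's
  +2.3 mL/min shift yields interaction p < 0.001 under SDs of 0.2–0.3,
  yet no subject crosses the 5 mL/min clinical threshold: every primary
  status is NO_CHANGE and nobody worsens anywhere — the "statistically
  significant but not clinically meaningful" demonstration. The arm size
  (40) and thresholds are package choices; only the table moments are fixed
  externally.

## What the synthetic data does and does not show

The generator emulates two-arm, two-timepoint designs with normal-ish
marginals, a fixed test-retest correlation, and response mixes enforced by
construction. It does not model dropout processes (missing counts are
fixed), floor/ceiling effects, skewed outcomes, or measurement rounding. A
passing suite therefore demonstrates that the classification, summary and
rendering machinery is correct and deterministic — not that any particular
clinical dataset will show these response patterns.

## Numerical choices and limitations

* Values parse as decimal reals; no unit conversion is attempted (units are
  display metadata). Missing cells are empty or `NA` (case-insensitive);
  any other non-numeric token is a loud `FormatError`.
* Threshold boundary ties count as change; quantile cut ties go central
  (both above).
* ANOVA sums of squares are clamped at 0 against floating-point residue of
  catastrophic cancellation; F statistics match independent recomputation
  to 1e-10 relative tolerance in tests.
* The permutation cross-check of the ANOVA tolerates 0.05 absolute
  disagreement: Monte-Carlo noise at 10,000 shuffles plus the discreteness
  of small-sample permutation distributions.
* Designs beyond 2 arms × 2 timepoints (crossover, longitudinal, >2 arms)
  are out of scope throughout, as are inference on statuses and
  multiplicity adjustment.
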