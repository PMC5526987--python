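# Methods

## Measurement model

A DNA-halo micrograph is treated as an 8-bit intensity field. All
quantities are defined on the 0–255 scale; deeper images are rejected
rather than rescaled so that configured thresholds keep their meaning. RGB
input is collapsed to one channel before analysis. The default policy is
the per-pixel maximum over R/G/B: the red fluorescence signal is recorded
through a long-pass filter onto a color camera and the receiving channel is
not guaranteed, so the maximum is robust to channel assignment. Explicit
`red`/`green`/`blue`/`luminance` policies are available when the channel is
known.

Candidate cells are the 8-connected components of pixels at or above a
coarse **seed threshold** (default 15, the most permissive outer threshold
in use — detection can then never miss an object the outer threshold could
measure). Components smaller than `min_object_area_px` are discarded as
debris, and components touching the frame border are dropped by default
because their areas are truncated and would bias radii (`border_policy =
"keep"` retains them). Each object carries its **local maximum** `M` and
the position of its maximum pixel, ties broken topmost-then-leftmost so
every run is deterministic.

Two regions are segmented per object, both as the 8-connected component of
pixels `≥ threshold` containing the object's maximum pixel (membership is a
closed lower bound; the threshold is clipped at 1 because a threshold of 0
would select the whole frame):

* the **residual nucleus (RN)** at `M − x` (`x = rn_offset_x`, e.g. 55 or
  75);
* the **outer halo** at either an absolute intensity (`x55/15` style) or at
  `M − B` relative to the maximum (`x75/x180` style).

Growing both regions from the same seed pixel links them positionally and
guarantees the RN is nested inside the outer region whenever the RN
threshold exceeds the outer threshold. In relative mode that ordering is
enforced at configuration time (`x < B`); in absolute mode a dim object can
invert it, in which case the RN is reported unmeasurable (`rn_fail`) for
that object rather than producing a non-nested "RN".

Thresholds that would fall below 1 are *absent* and the region is
unmeasurable: `rn_fail` when `M − x < 1` (the class-II condition) and
`outer_fail` when `M − B < 1` in relative mode (the decay failure event).
Per-object failures are encoded in the measurement status; measuring a
field never raises.

Areas convert to radii by the equal-area-circle convention
`r = √(A/π)` — the same convention as the polygon-trace visual method the
thresholds are calibrated against — and the halo radius is
`outer radius − RN radius`.

Thresholds are anchored to **per-object** maxima by default, which is what
makes one configuration usable across a population whose cells differ
widely in brightness. A `maxima_scope="image"` switch anchors every object
to the brightest detected object's maximum instead, for fidelity
experiments against single-maximum implementations.

## Classification

Classes reflect decreasing DNA:NM attachment stability. Class **II** is
defined operationally as RN-measurement failure at the classifier's own
offset. For measurable RNs the bright fraction
`f = #(RN pixels > 220) / RN area` splits class **Ia** (`f > 0.5`) from
**Ib** (`f ≤ 0.5`). Both comparisons are strict: "above 220" excludes
pixels at exactly 220, and an exact 50 % tie is pale (Ib), so the
measure-zero boundary is still deterministic. The classifier re-segments
the RN with its own offset (`RNx75/RN220`, `RNx55/RN220`) rather than
reusing whichever offset sized the halos: the two analyses are named as
distinct variants and must be independently configurable.

## Stability

One cell is tracked across its frames by nearest centroid within a 50 px
displacement gate; at the first frame, where no previous centroid exists,
the largest detected object is taken (fields for stability imaging contain
an individual cell, so this is ordinarily unambiguous). The decay record is
the time of the first frame whose measurement status is not `measured`,
including frames where the tracked object vanishes below the seed threshold
or leaves the gate. A frame that becomes measurable again after a failure
never rescinds it — one decay time per cell — but the transient is kept in
the record's note for audit. Cells measurable at every frame are censored
at a configurable sentinel, 70 s by default for the 0–60 s series.
Population summaries are the raw percent of surviving halos per time point
(censored cells survive every observed time) and the mean ± SEM of fail
times with censored cells contributing the sentinel — deliberately not a
Kaplan–Meier estimator, which is out of scope for this assay's convention.

## Calibration and statistics

`percent_of_reference` averages per-pair percents `100·derived/reference`
(per-pair first, then mean — matching how mean derived radii are reported
as percentages of visually derived values). `calibrate_rn_offset` sweeps
candidate offsets over a training set of (image, visual radius) pairs and
selects the offset minimizing `|mean percent − 100|`; that absolute
deviation from parity is the minimal loss consistent with choosing the
setting that "returns ~100 % of visual estimates", and ties go to the
smaller offset. Candidates that measure no RN on any training image are
excluded from selection but reported.

Group comparisons use the two-sample **equal-variance** Student's t-test
(no variance qualifier is attached to the assay's convention, so Welch is
not substituted), two-sided, with significance stars at p < 0.05 / 0.005 /
0.0005. SEM uses the n−1 sample standard deviation and is reported absent
for n = 1.

`polygon_radius` reproduces the visual sizing primitive: shoelace area of a
simple polygon, converted by the same equal-area-circle rule.
Self-intersecting or degenerate polygons are rejected.

## Synthetic phantoms

The generator emulates what the pipeline consumes — a bright near-circular
RN with a radially decaying halo on a noisy background — not the biology
that produces it (no salt extraction, supercoiling or strand-break
physics). The radial profile is a plateau at peak `P` inside the RN radius
`a` with a Gaussian tail of decay length `s`:

```
I(r) = b + (P − b)                         r ≤ a
I(r) = b + (P − b)·exp(−((r − a)/s)²)      r > a
```

The Gaussian tail is chosen because every threshold crossing is then closed
form, `r(t) = a + s·√ln((P−b)/(t−b))`, turning the generator into an
oracle for the measurement chain. A "peaked" variant (pure Gaussian from
the center) is available; the profile is pluggable. Multi-phantom fields
take the pixel-wise maximum over profiles; phantoms must not overlap above
background and must fit inside the frame (otherwise ground truth would be
ill-defined), and one field shares a single background and noise level.
Noise is additive Gaussian, clipped to [0, 255] and rounded — a simple
stand-in for camera noise; rendering is bit-reproducible given a seed.

Timed series decay the peak multiplicatively, `P(t) = b + (P₀−b)·e^(−kt)`.
The analytic fail frame is the first frame where the *rendered* (rounded)
peak satisfies `round(P(t)) − B < 1`, matching exactly what the 8-bit
measurement sees; the decay sampler rejects rates whose peak lands within
0.3 intensity units of the rounding boundary at any frame so the crossing
frame is never ambiguous.

Default frame size for full-scale simulation mirrors the 1388 × 1040 px
capture format. Test and benchmark suites render each phantom in the
smallest frame containing its support plus a margin (typically 150–300 px
square) and lower the debris floor to `min_object_area_px = 200`
accordingly — the 500 px default is sized for full micrographs, where an RN
radius of 10 px (area ≈ 314 px) would otherwise sit below the floor on
small synthetic frames. Recovery phantoms use peak 255 on background 0 with
RN cores of 2–20 px and halo scales of 17–40 px, which places RN crossings
near 10–40 px and halo widths near 20–50 px under `x55/15`; class phantoms
put intents at least 10 intensity units clear of every classifier cut
(Ia saturated at 255, Ib peaks 190–210, II peaks 30–45).

## What the phantom results do and do not show

Passing recovery suites show the measurement chain is correct against its
own intensity model: thresholds computed and applied exactly, regions
linked and nested, areas converted consistently, decay timing faithful to
the rendered intensities. They do not show that the thresholds are
biologically right for a given microscope, stain or cell line — real halos
are irregular, backgrounds uneven, debris plentiful and profiles not
Gaussian. The calibration operations exist precisely because those choices
must be re-anchored per apparatus (exposure against an NM marker; RN offset
against a visual training set).

## Numerical choices and benchmark sizes

Radius-recovery benchmarks use 50 single-phantom fields per condition
(noise-free tolerance 1 px; σ = 5 tolerance 2 px), classification uses 200
phantoms, decay uses 32 series of 7 frames (the assay's typical 8 cells ×
4 coverslips), calibration uses 20 independent training sets of 5 images,
and the t-test's null rejection rate uses 4000 simulated pairs of n = 10 —
enough that the Monte Carlo error of the rate estimate is small against the
[3.6 %, 6.4 %] acceptance band. The full test suite runs in well under a
minute on one CPU.

## Known limitations

* Segmentation is pure intensity thresholding with no sub-pixel edge
  localization, by design; radii inherit half-pixel rasterization jitter.
* Touching cells merge into one candidate object; the generator refuses to
  render overlapping phantoms rather than modelling the ambiguity.
* Tracking is nearest-centroid with a fixed gate — adequate for
  single-cell stability fields, not for dense time-lapse scenes.
* The decay model is phenomenological (exponential peak decay); real
  photo-induced decay need not be exponential, and only the threshold
  crossing, not the decay shape, is used.
* Class II is *defined* as RN-measurement failure, so its prevalence
  depends on the classifier's offset; distributions are only comparable at
  a fixed configuration.
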