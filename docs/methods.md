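# Methods

This note documents the models, rules and numerical choices in `ichscreen`,
what the synthetic phantoms do and do not establish, and where the design
was genuinely open.

## The screening model

The pipeline treats hemorrhage screening as a per-slice multi-label problem
followed by deterministic aggregation. Each axial slice yields six scores
in [0, 1]: one per subtype (IPH, IVH, SAH, SDH, EDH) and one "Any" head
indicating blood of some kind on the slice. The heads are independent
sigmoid-style outputs, not a softmax, because subtypes co-occur (a
contusion with subdural blood is one case, two labels).

**Windowing.** HU values are mapped through a display window
(WL = level, WW = full width) as `clip((v − (WL − WW/2)) / WW, 0, 1)` —
linear inside `[WL − WW/2, WL + WW/2]`, clipped outside, monotone
everywhere. Three standard head windows (brain 30/80, subdural 80/200,
bone 600/2800) are stacked into one 3-channel image. Channels stay in
floating [0, 1] internally; quantization to 8-bit happens only at PNG
export (value → round(255·v), half up), so the classifier interface is not
committed to a byte dialect.

**Decision rule.** Per label, a threshold θ is calibrated on labeled scores
by maximizing SEN(θ) + SPEC(θ), the Youden-style optimum on the ROC curve.
Positivity is strict (`score > θ`): a score exactly at threshold is
negative, covered by a boundary test. Candidate cuts are 0 plus the
distinct score values; with the strict rule these realize every achievable
classification, each at its smallest cut, and among ties the smallest θ is
returned — the sensitivity-favoring choice, appropriate for an alert
system where false negatives are the costly error. A slice is positive for
subtype *t* only when both `p_t > θ_t` and `p_Any > θ_Any`; a case is
positive when at least one slice retains a detection after
post-processing. Thresholds are calibrated independently per label.

**Vertex false-positive suppression.** Beam hardening and scatter near
dense bone produce hyperdense streaks that mimic blood, concentrated where
the skull curves over the brain. The rule set:

1. *TIV segmentation*: per slice, pixels strictly inside the brain-window
   span (−10, 70) HU; largest connected component (scalp soft tissue also
   falls in range on real scans); interior holes filled. Areas in mm².
2. *Upper-slice flagging*: a slice is "upper" iff its TIV area ratio to the
   volume's maximum TIV area is strictly below 0.4. The maximum-area slice
   has ratio 1 and is never upper; ratios are scale-free, so pixel counts
   and mm² give identical flags.
3. *Suppression*: a detection on an upper slice is removed unless a
   detection of the *same* subtype exists on a directly adjacent slice
   (first/last slices consult their single neighbor — forced by geometry).
   The decision consults the **original** detection map in a single pass:
   an iterative cascade could remove one member of a genuinely paired
   (two-consecutive-slice) detection and then the other, contradicting the
   persistence criterion the rule encodes. Consequently the operation never
   adds detections and never touches non-upper slices.

Whether a production system should consult original or post-removal
neighbor detections is an interpretation point; the single-pass
original-map semantics is the one implemented and property-tested against
a brute-force per-(slice, subtype) oracle.

**Reporting.** Findings are slice-granular (one per surviving
slice × subtype flag) and carry a verbal grade: probable (< 0.80), very
probable ([0.80, 0.95)), almost certain (≥ 0.95). The band edges are
reporting conventions of this package — configurable, left-closed above —
not published cutoffs. Reports are JSON with the full materialized
parameter set and per-stage timestamps, so every verdict is auditable.

## The reference classifier

The deterministic heuristic exists so the pipeline's rules can be tested
end-to-end without trained weights; it is a contract reference, not a
clinical claim. It recovers approximate HU by inverting the subdural
channel (the widest unclipped soft-tissue window), Gaussian-smooths
(σ = 1 px), and takes the fraction of intracranial pixels in the acute
blood band [50, 90] HU. A 3σ rim along the mask edge is excluded because
smoothing drags skull-adjacent values through the band. The fraction maps
through a fixed logistic (midpoint 0.002, scale 0.0008): an empty band
gives a baseline score ≈ 0.076, a 1% intracranial blood fraction
saturates. Subtype assignment is geometric per connected component:
majority ventricle-map overlap → IVH; median distance to the intracranial
rim > 8 mm → IPH; peripheral and thinner than 4.5 mm → SAH; peripheral,
thick, arc span > 70° → SDH; else EDH. All constants are config
parameters.

The optional trainable hook (`fit_small_model`) fits six independent
logistic regressions over summary image features, minimizing per-label
binary cross-entropy, reproducible per seed. It demonstrates the plugin
contract at desk scale; it is not the accepted analysis path.

## Evaluation framework

Scoring is case-wise and binary (subtype labels are ignored): one reading
is ground truth, the other is categorized TP/FN/FP/TN, and
SEN = TP/(TP+FN), SPEC = TN/(TN+FP), FPR = 1 − SPEC, PPV, NPV, ACC and
BalACC = (SEN+SPEC)/2 follow. Undefined metrics (zero denominators) raise
a named error instead of returning NaN, because silent NaNs would corrupt
mean rows. Display rounding is half-up to 2 decimals; internal values are
never rounded.

Mean rows over several comparisons average counts arithmetically and
average the **unrounded** per-comparison metrics (canonical). The average
of the rounded metrics is emitted alongside: published tables are
sometimes assembled by averaging already-rounded entries, and with
sensitivities like 0.94/0.85 the two conventions differ at the second
decimal (0.89 vs 0.90). Both are inspectable; neither is silently chosen
for the user.

The rating data model mirrors two-step reader studies: independent initial
verdicts, re-evaluation of discordant cases with the option to confirm or
revise, `final = revised if present else initial`. Cases lacking a final
verdict from either rater are excluded and reported, not scored.

## Phantoms: what they emulate, and what passing tests show

Phantoms are geometric heads: skull shell +1000 HU (6 mm), parenchyma
35 HU, CSF ventricles 5 HU on the mid slices, air −1000 HU, additive
Gaussian noise (sd 4 HU — a realistic quantum-noise level for a head
protocol). Default geometry is 30 slices × 256×256 at 0.9 mm pixels and
4 mm thickness, chosen for test speed; a 512 matrix is available. The
intracranial radius (75 mm) tapers as a hemispherical cap over the top
third of slices, guaranteeing slices below the 0.4 TIV ratio. Lesions use
subtype-conventional shapes (IPH disc deep in parenchyma, IVH disc inside
the ventricles, SAH 3 mm ribbon under the surface, SDH 10 mm crescent over
a 120° arc, EDH 12 mm lens over 44°) at 55–90 HU; streak artifacts are
80 HU bars confined to exactly one vertex slice and are *not* labeled as
hemorrhage. Rasterization is a pixel-center test with no antialiasing, so
the ground-truth TIV mask and the threshold segmentation agree exactly up
to noise.

What passing phantom tests establish: the windowing, calibration,
binarization, TIV/upper-slice/suppression and aggregation rules compose
correctly and recover exactly-known truth deterministically. What they do
not establish: classifier performance on real anatomy (partial volume,
scalp, skull-base geometry, pathology variety), robustness of the TIV
recipe to real soft tissue, or any clinical operating point. The
large-scale trained-CNN path that a production system would use is out of
scope here by design; only its contract is reproduced.

## Numerical choices and degenerate inputs

- DICOM round-trip stores int16 with slope 1/intercept 0 → read-back
  within 0.5 HU; files without rescale tags are refused, never guessed.
- Slice order: image-position z ascending, instance number as tie-break;
  adjacency in the suppression rule is defined by this physical order.
- `min_slices` defaults to 20 (a whole-head 4–5 mm protocol); the
  protocol minimum is site-specific and configurable.
- TIV: both brain-window bounds are used as strict cutoffs; a volume with
  no in-range pixel anywhere raises (the area ratio would be undefined);
  individual empty slices get area 0 and are therefore upper.
- Calibration requires both classes; single-class label sets raise.
- Grading bands partition [0, 1] totally; every probability gets exactly
  one grade.
- The classifier context mask in the pipeline is the skull-enclosed cavity
  (holes of the bone-density region, > 300 HU) united with the TIV mask:
  peripheral collections above the brain-window upper bound carve bites out
  of the thresholded TIV but remain enclosed by bone. On real scans with
  open skull-base geometry this recipe is approximate — a documented
  limitation.

## Problem sizes

The shipped test and acceptance runs use the default phantom geometry
(30 × 256 × 256), an 11-case fixture suite, 6 calibration phantoms, 1,000
random detection matrices for the suppression oracle and 200 random score
sets (n ≤ 200) for the calibration oracle. These sizes were chosen as the
package's standard desk-scale configuration; all are parameters.

## Known limitations

- The reference classifier's geometric subtype rules are tuned to the
  phantom shape conventions; real lesion morphology is far richer.
- TIV segmentation is not a skull-stripping method; it is exactly the
  thresholded-largest-component recipe the suppression rule needs.
- Multi-frame enhanced CT, DICOM networking, and report transport formats
  are out of scope; JSON is the canonical report artifact.
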