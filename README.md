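# ichscreen

A screening pipeline for intracranial hemorrhage (ICH) on non-contrast
cranial CT, built the way deployed triage systems are structured: per-slice
classification behind a pluggable contract, with all the deterministic
machinery around it — preprocessing, threshold calibration, geometric
false-positive suppression, case-level reporting, and reader-agreement
evaluation — implemented as an auditable, testable library and CLI.

## What it does

Given an axial head CT series (classic DICOM, one file per slice), the
pipeline:

1. **Reads and validates** the series: pixel data are converted to
   Hounsfield units (HU) via each file's rescale slope/intercept, slices are
   ordered by physical position, and series with fewer slices than the
   protocol minimum are rejected rather than analyzed.
2. **Windows** each slice three ways — brain (WL 30 / WW 80), subdural
   (WL 80 / WW 200) and bone (WL 600 / WW 2800) — and stacks the renderings
   into a 3-channel image, the standard input representation for ICH
   slice classifiers.
3. **Classifies** each slice into six probabilities: one per subtype
   (intraparenchymal IPH, intraventricular IVH, subarachnoid SAH, subdural
   SDH, epidural EDH) plus an "Any" head. The classifier is a plugin; the
   package ships a deterministic intensity-and-geometry reference
   implementation plus an optional small trainable hook.
4. **Binarizes** with per-label thresholds θ calibrated Youden-style:
   θ maximizes SEN(θ) + SPEC(θ) over the ROC curve. A slice is positive for
   subtype *t* iff p<sub>t</sub> > θ<sub>t</sub> **and**
   p<sub>Any</sub> > θ<sub>Any</sub>.
5. **Suppresses vertex artifacts**: the total intracranial volume (TIV) is
   segmented per slice at the brain-window span; a slice whose TIV area is
   below 0.4 of the volume's maximum TIV area is an "upper" slice, and a
   detection there is removed unless the same subtype was detected on a
   directly adjacent slice. This targets beam-hardening streaks near the
   skull vertex that mimic blood but do not persist across slices.
6. **Aggregates** to a case verdict — positive iff any slice retains a
   detection — and writes a structured JSON report with per-finding slice
   index, subtype, probability and verbal grade (probable / very probable /
   almost certain), the full parameter set, and stage timestamps.

Evaluation mirrors clinical reader studies: per-case binary verdicts from
two raters (with a two-step independent-rating/adjudication model), 2×2
contingency tables with one reading as ground truth, and the standard
metric set SEN, FPR, SPEC, PPV, NPV, ACC and balanced accuracy
(SEN + SPEC)/2, including mean-of-comparison summary rows.

Because clinical data cannot ship with the package, everything is testable
on **synthetic phantoms**: geometric heads with a bone-density skull,
parenchyma, CSF ventricles, subtype-conventional hyperdense lesions, and
single-slice vertex streaks, all with exact ground truth.

## Worked example

```bash
# generate the standard phantom suite (11 named cases, exact ground truth)
ichscreen phantom --seed 7 --out /tmp/suite

# analyze one case
ichscreen analyze /tmp/suite/sdh
```

prints

```
sdh: POSITIVE (6 findings)
  slice   8  SDH  p=1.000  almost certain
  slice   9  SDH  p=1.000  almost certain
  slice  10  SDH  p=1.000  almost certain
  slice  11  SDH  p=1.000  almost certain
  slice  12  SDH  p=1.000  almost certain
  slice  13  SDH  p=1.000  almost certain
```

i.e. the subdural-crescent phantom is positive, with the SDH lesion found
on exactly the six slices where it was painted, each graded by its
probability. The artifact-only case shows the suppression rule working:

```bash
ichscreen analyze /tmp/suite/artifact_only                       # negative
ichscreen analyze /tmp/suite/artifact_only --no-postprocessing   # POSITIVE
```

The vertex streak is detected by the classifier but removed by the
adjacency rule, because it appears on a single upper slice only.

Batch and evaluation:

```bash
ichscreen batch /tmp/suite/manifest.json --out /tmp/out
ichscreen evaluate /tmp/out/predictions.csv ratings.csv
```

`evaluate` prints one row per ground-truth comparison with columns
TP FN FP TN SEN FPR SPEC PPV NPV ACC BalACC plus mean rows.

## Layout

| module | contents |
| --- | --- |
| `ichscreen.ct_io` | DICOM series read/write, HU conversion, protocol validation |
| `ichscreen.windowing` | display windows, tri-window composition, PNG export |
| `ichscreen.classifier` | classifier contract, reference heuristic, Youden calibration, binarization, small trainable hook |
| `ichscreen.postprocess` | TIV segmentation, upper-slice flagging, vertex-artifact suppression |
| `ichscreen.aggregation` | case verdicts, probability grading, JSON reports |
| `ichscreen.evaluation` | contingency tables, metric set, mean rows, adjudication, ratings CSV |
| `ichscreen.phantom` | phantom generator and the standard fixture suite |
| `ichscreen.pipeline`, `ichscreen.cli`, `ichscreen.config` | orchestration, CLI, configuration |

See `docs/methods.md` for the model, parameter and design documentation.
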