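"""End-to-end orchestration: read -> validate -> window -> classify ->
TIV -> upper-slice flagging -> artifact suppression -> case aggregation.

The per-stage wall-clock timings echo the audit-trail idea of time-stamping
each processing step; only local compute stages are timed (transport is a
deployment property, not a pipeline one).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from .aggregation import CaseFinding, aggregate_case, write_report
from .classifier import (
    SUBTYPES,
    HeuristicSliceClassifier,
    LabeledScoreSet,
    SliceContext,
    SubtypeProbabilities,
    ThresholdSet,
    calibrate_threshold,
)
from .config import PipelineConfig
from .ct_io import CTVolume, SeriesValidationReport, read_dicom_series, validate_series
from .errors import ICHScreenError, ParameterError
from .phantom import PhantomSpec, generate_phantom
from .postprocess import (
    DetectionMap,
    TIVMask,
    UpperSliceFlags,
    flag_upper_slices,
    segment_tiv,
    suppress_vertex_artifacts,
)
from .windowing import TriWindowImage, compose_tri_window

__all__ = [
    "StageTimings",
    "CaseResult",
    "build_classifier",
    "build_slice_contexts",
    "classify_volume",
    "run_case",
    "run_batch",
    "run_evaluation",
    "calibrate_thresholds_on_phantoms",
    "dominant_subtype",
]

logger = logging.getLogger("ichscreen")

_STAGES = ("ingest", "preprocess", "classify", "postprocess", "report")


@dataclass
class StageTimings:
    durations: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.durations.values())


@dataclass
class CaseResult:
    """Everything run_case produces for one series."""

    case_id: str
    finding: Optional[CaseFinding]
    validation: SeriesValidationReport
    timings: StageTimings
    detections_raw: Optional[DetectionMap] = None
    detections: Optional[DetectionMap] = None
    probs: Optional[list[SubtypeProbabilities]] = None
    tiv: Optional[TIVMask] = None
    upper: Optional[UpperSliceFlags] = None


def build_classifier(config: PipelineConfig):
    if config.classifier.kind == "heuristic":
        return HeuristicSliceClassifier(**config.classifier.params)
    raise ParameterError(f"unknown classifier kind {config.classifier.kind!r}")


def build_slice_contexts(
    volume: CTVolume, tiv: TIVMask, config: PipelineConfig
) -> list[SliceContext]:
    """Per-slice classifier context from the TIV segmentation and the skull.

    The classification mask is the skull-enclosed cavity (holes of the
    bone-density region) united with the TIV mask: hyperdense peripheral
    collections lie above the brain-window upper bound and so carve bites
    out of the thresholded TIV, but they are still intracranial — enclosed
    by bone.  The ventricle map is the CSF-range region (on the smoothed
    slice, to reject single noise pixels) dilated by 8 mm, so blood inside
    or beside the ventricles overlaps it.
    """
    contexts = []
    dil_px = max(1, int(round(8.0 / volume.pixel_spacing[0])))
    selem = morphology.disk(dil_px).astype(bool)
    for i in range(volume.n_slices):
        mask = tiv.mask[i]
        bone = volume.slices[i] > 300.0
        cavity = ndimage.binary_fill_holes(bone) & ~bone if bone.any() else bone
        smooth = ndimage.gaussian_filter(volume.slices[i], sigma=1.0)
        csf = (smooth > -10.0) & (smooth < 20.0) & mask
        vent = ndimage.binary_dilation(csf, structure=selem) if csf.any() else csf
        contexts.append(
            SliceContext(
                tiv_mask=cavity | mask,
                pixel_spacing=volume.pixel_spacing,
                ventricle_mask=vent,
            )
        )
    return contexts


def classify_volume(
    volume: CTVolume,
    config: PipelineConfig,
    classifier=None,
    tiv: Optional[TIVMask] = None,
) -> tuple[list[TriWindowImage], list[SubtypeProbabilities], TIVMask]:
    """Window and classify every slice; returns images, probabilities, TIV."""
    classifier = classifier or build_classifier(config)
    specs = config.windows.specs()
    if tiv is None:
        tiv = segment_tiv(
            volume,
            hu_low=config.postprocess.tiv_hu_low,
            hu_high=config.postprocess.tiv_hu_high,
        )
    contexts = build_slice_contexts(volume, tiv, config)
    images = [
        compose_tri_window(volume.slices[i], specs, slice_index=i)
        for i in range(volume.n_slices)
    ]
    probs = [classifier.classify(img, ctx) for img, ctx in zip(images, contexts)]
    return images, probs, tiv


def _binarize_volume(probs: list[SubtypeProbabilities], thresholds: ThresholdSet) -> DetectionMap:
    from .classifier import binarize

    flags = np.zeros((len(probs), len(SUBTYPES)), dtype=bool)
    for i, p in enumerate(probs):
        det = binarize(p, thresholds)
        flags[i] = [det[s] for s in SUBTYPES]
    return DetectionMap(flags=flags)


def run_case(
    dicom_dir,
    config: Optional[PipelineConfig] = None,
    out: Optional[Path] = None,
    emit_composites: bool = False,
    case_id: Optional[str] = None,
    apply_postprocessing: bool = True,
) -> CaseResult:
    """Run the full pipeline on one DICOM series directory.

    A series failing protocol validation yields a CaseResult with
    ``finding=None`` and the validation report — a rejection, not an error.
    ``apply_postprocessing=False`` skips the vertex-artifact suppression
    step (for effect-direction comparisons).
    """
    config = config or PipelineConfig()
    case_id = case_id or Path(dicom_dir).name
    timings = StageTimings()
    stamps = {}

    t0 = time.perf_counter()
    volume = read_dicom_series(dicom_dir)
    timings.durations["ingest"] = time.perf_counter() - t0
    logger.info("case=%s ingested %d slices", case_id, volume.n_slices)

    validation = validate_series(volume, min_slices=config.io.min_slices)
    if not validation.passed:
        logger.warning("case=%s rejected: %s", case_id, validation.reasons)
        return CaseResult(case_id=case_id, finding=None, validation=validation, timings=timings)

    t0 = time.perf_counter()
    images, probs, tiv = classify_volume(volume, config)
    timings.durations["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    raw = _binarize_volume(probs, config.thresholds.threshold_set())
    upper = flag_upper_slices(tiv, threshold=config.postprocess.upper_ratio_threshold)
    detections = suppress_vertex_artifacts(raw, upper) if apply_postprocessing else raw
    timings.durations["postprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    finding = aggregate_case(
        detections, probs, case_id=case_id, grading_bands=config.grading.edges
    )
    if out is not None:
        stamps = {s: pd.Timestamp.now().isoformat() for s in _STAGES}
        composites = (
            {f.slice_index: images[f.slice_index] for f in finding.findings}
            if emit_composites
            else None
        )
        write_report(
            finding,
            out,
            parameters=config.to_dict(),
            timestamps=stamps,
            composites=composites,
        )
    timings.durations["report"] = time.perf_counter() - t0
    logger.info(
        "case=%s verdict=%s findings=%d", case_id, finding.positive, len(finding.findings)
    )

    return CaseResult(
        case_id=case_id,
        finding=finding,
        validation=validation,
        timings=timings,
        detections_raw=raw,
        detections=detections,
        probs=probs,
        tiv=tiv,
        upper=upper,
    )


def dominant_subtype(finding: CaseFinding) -> Optional[str]:
    """The subtype with the most finding slices (max probability tie-break)."""
    if not finding.findings:
        return None
    stats: dict[str, tuple[int, float]] = {}
    for f in finding.findings:
        count, best = stats.get(f.subtype, (0, 0.0))
        stats[f.subtype] = (count + 1, max(best, f.probability))
    return max(stats, key=lambda s: stats[s])


def run_batch(
    manifest_path,
    config: Optional[PipelineConfig] = None,
    out_dir=None,
    apply_postprocessing: bool = True,
) -> pd.DataFrame:
    """Run every case listed in a suite manifest; one prediction row per case.

    Per-case failures are logged and marked in the output, never abort the
    batch.  Writes ``predictions.csv`` (and per-case reports) into
    ``out_dir`` when given.
    """
    config = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)

    rows = []
    for case in manifest.get("cases", []):
        case_id = case["case_id"]
        dicom_dir = Path(case["dicom_dir"])
        if not dicom_dir.is_absolute():
            dicom_dir = manifest_path.parent / dicom_dir
        row: dict = {"case_id": case_id, "status": "ok", "positive": ""}
        for s in SUBTYPES:
            row[s.lower()] = ""
        try:
            report_path = Path(out_dir) / f"{case_id}.json" if out_dir else None
            result = run_case(
                dicom_dir,
                config,
                out=report_path,
                case_id=case_id,
                apply_postprocessing=apply_postprocessing,
            )
            if result.finding is None:
                row["status"] = "rejected:" + ",".join(result.validation.reasons)
            else:
                row["positive"] = int(result.finding.positive)
                for s in SUBTYPES:
                    row[s.lower()] = int(s in result.finding.subtypes_present)
                row["dominant_subtype"] = dominant_subtype(result.finding) or ""
        except Exception as exc:  # a corrupt case must not abort the batch
            logger.error("case=%s failed: %s", case_id, exc)
            row["status"] = f"failed:{type(exc).__name__}"
        rows.append(row)

    columns = ["case_id", "status", "positive"] + [s.lower() for s in SUBTYPES] + ["dominant_subtype"]
    df = pd.DataFrame(rows).reindex(columns=columns).fillna("")
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "predictions.csv", index=False)
    return df


def run_evaluation(predictions_csv, ratings_csv) -> pd.DataFrame:
    """Score predictions against each rater's final verdicts, Table-style.

    Emits one row per ground-truth comparison (each rater as GT vs the
    algorithm, each rater as GT vs the other rater) plus mean rows, with
    columns TP FN FP TN SEN FPR SPEC PPV NPV ACC BalACC.
    """
    from .evaluation import (
        METRIC_NAMES,
        adjudicate,
        build_contingency,
        compute_metrics,
        mean_of_comparisons,
        read_ratings_csv,
        round_half_up,
    )

    preds = pd.read_csv(predictions_csv, dtype={"case_id": str})
    preds = preds[preds["status"] == "ok"] if "status" in preds.columns else preds
    predicted = {str(r.case_id): int(r.positive) for r in preds.itertuples(index=False)}

    records = read_ratings_csv(ratings_csv)
    raters = sorted({r.rater_id for r in records})
    if len(raters) != 2:
        raise ParameterError(f"exactly two raters required, found {raters}")
    r1 = [r for r in records if r.rater_id == raters[0]]
    r2 = [r for r in records if r.rater_id == raters[1]]
    adj = adjudicate(r1, r2)

    scored = {cid for cid in adj.finals if cid in predicted}
    finals1 = {cid: adj.finals[cid][0] for cid in scored}
    finals2 = {cid: adj.finals[cid][1] for cid in scored}
    pred = {cid: predicted[cid] for cid in scored}

    comparisons = [
        (f"{raters[0]}(GT) vs. AI", finals1, pred),
        (f"{raters[1]}(GT) vs. AI", finals2, pred),
        (f"{raters[0]}(GT) vs. {raters[1]}", finals1, finals2),
        (f"{raters[1]}(GT) vs. {raters[0]}", finals2, finals1),
    ]

    rows = []

    def metric_row(name, table, metrics: dict) -> dict:
        row = {"comparison": name, "TP": table["tp"], "FN": table["fn"],
               "FP": table["fp"], "TN": table["tn"]}
        for m in METRIC_NAMES:
            row[m.upper() if m != "balacc" else "BalACC"] = round_half_up(metrics[m])
        return row

    ai_tables, ai_metrics, ir_tables, ir_metrics = [], [], [], []
    for name, truth, predicted_map in comparisons:
        table = build_contingency(truth, predicted_map)
        metrics = compute_metrics(table)
        (ai_tables if "AI" in name else ir_tables).append(table)
        (ai_metrics if "AI" in name else ir_metrics).append(metrics)
        rows.append(metric_row(name, {k: getattr(table, k) for k in ("tp", "fn", "fp", "tn")},
                               metrics.as_dict()))

    for label, tables, metrics in (
        ("Mean AI vs. rater", ai_tables, ai_metrics),
        ("Mean inter-rater", ir_tables, ir_metrics),
    ):
        summary = mean_of_comparisons(metrics, tables)
        rows.append(metric_row(label, summary.mean_counts, summary.mean_metrics))

    return pd.DataFrame(rows)


def calibrate_thresholds_on_phantoms(
    specs: list[PhantomSpec], config: Optional[PipelineConfig] = None
) -> ThresholdSet:
    """Calibrate every label's threshold on a set of phantoms with known truth.

    Runs the configured classifier over all slices of all phantoms, pools
    scores per label with the phantom ground truth, and applies the
    Youden-style cut per label independently.
    """
    config = config or PipelineConfig()
    classifier = build_classifier(config)
    scores: dict[str, list[float]] = {s: [] for s in SUBTYPES + ("Any",)}
    labels: dict[str, list[int]] = {s: [] for s in SUBTYPES + ("Any",)}
    for spec in specs:
        volume, truth = generate_phantom(spec)
        _, probs, _ = classify_volume(volume, config, classifier=classifier)
        for i, p in enumerate(probs):
            row = p.as_dict()
            for j, s in enumerate(SUBTYPES):
                scores[s].append(row[s])
                labels[s].append(int(truth.slice_labels[i, j]))
            scores["Any"].append(row["Any"])
            labels["Any"].append(int(truth.slice_labels[i].any()))

    theta = {}
    for name in SUBTYPES + ("Any",):
        theta[name] = calibrate_threshold(
            LabeledScoreSet(scores=np.array(scores[name]), labels=np.array(labels[name]))
        )
    return ThresholdSet.from_dict(theta)
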