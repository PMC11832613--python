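"""Case-level aggregation and the structured findings report.

A case (all slices of one patient) is positive when at least one slice
carries a surviving detection.  Each surviving (slice, subtype) flag becomes
a finding, graded into the verbal probability scale used in clinical
reporting — probable, very probable, almost certain — by configurable band
edges (defaults 0.80/0.95; the bands are reporting conventions of this
package, not published cutoffs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .classifier import SUBTYPES, SubtypeProbabilities
from .errors import GeometryError, ParameterError
from .postprocess import DetectionMap

__all__ = [
    "GRADES",
    "DEFAULT_GRADING_BANDS",
    "SliceFinding",
    "CaseFinding",
    "grade_probability",
    "aggregate_case",
    "write_report",
    "read_report",
]

GRADES = ("probable", "very probable", "almost certain")
DEFAULT_GRADING_BANDS = (0.80, 0.95)


@dataclass(frozen=True)
class SliceFinding:
    slice_index: int
    subtype: str
    probability: float
    grade: str


@dataclass
class CaseFinding:
    """Case verdict: positive iff any finding survived post-processing."""

    case_id: str
    n_slices_evaluated: int
    findings: list[SliceFinding] = field(default_factory=list)

    @property
    def positive(self) -> bool:
        return bool(self.findings)

    @property
    def subtypes_present(self) -> set[str]:
        return {f.subtype for f in self.findings}


def grade_probability(p: float, bands: tuple[float, float] = DEFAULT_GRADING_BANDS) -> str:
    """Map a probability to a verbal grade; bands are left-closed above.

    p < edge1 -> probable; edge1 <= p < edge2 -> very probable;
    p >= edge2 -> almost certain.
    """
    e1, e2 = bands
    if not (0.0 < e1 < e2 < 1.0):
        raise ParameterError(f"grading edges must be ascending within (0,1), got {bands}")
    if p < e1:
        return GRADES[0]
    if p < e2:
        return GRADES[1]
    return GRADES[2]


def aggregate_case(
    detections: DetectionMap,
    probs: list[SubtypeProbabilities],
    case_id: str = "",
    grading_bands: tuple[float, float] = DEFAULT_GRADING_BANDS,
) -> CaseFinding:
    """Turn the post-processed detection map into a case-level verdict.

    One finding per surviving (slice, subtype) flag, carrying that subtype's
    probability on that slice and its verbal grade.
    """
    if len(probs) != detections.n_slices:
        raise GeometryError(
            f"{len(probs)} probability rows for {detections.n_slices} detection rows"
        )
    findings: list[SliceFinding] = []
    for i in range(detections.n_slices):
        row = probs[i].as_dict()
        for t, subtype in enumerate(SUBTYPES):
            if detections.flags[i, t]:
                p = row[subtype]
                findings.append(
                    SliceFinding(
                        slice_index=i,
                        subtype=subtype,
                        probability=p,
                        grade=grade_probability(p, grading_bands),
                    )
                )
    return CaseFinding(
        case_id=case_id, n_slices_evaluated=detections.n_slices, findings=findings
    )


def write_report(
    case: CaseFinding,
    path,
    parameters: dict | None = None,
    timestamps: dict | None = None,
    composites: dict[int, "object"] | None = None,
) -> Path:
    """Write the structured JSON findings report; optionally PNG composites.

    ``composites`` maps slice index to a TriWindowImage; each is exported
    next to the report as ``<stem>_slice<idx>.png``.
    """
    from .windowing import export_composite_png

    path = Path(path)
    payload = {
        "case_id": case.case_id,
        "positive": case.positive,
        "n_slices_evaluated": case.n_slices_evaluated,
        "findings": [
            {
                "slice_index": f.slice_index,
                "subtype": f.subtype,
                "probability": f.probability,
                "grade": f.grade,
            }
            for f in case.findings
        ],
        "parameters": parameters or {},
        "timestamps": timestamps or {},
    }
    composite_paths = []
    if composites:
        for idx in sorted(composites):
            png = path.with_name(f"{path.stem}_slice{idx}.png")
            export_composite_png(composites[idx], png)
            composite_paths.append(png.name)
    if composite_paths:
        payload["composites"] = composite_paths
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path


def read_report(path) -> CaseFinding:
    """Parse a report back into a CaseFinding (round-trip identity)."""
    with open(path) as fh:
        payload = json.load(fh)
    findings = [
        SliceFinding(
            slice_index=f["slice_index"],
            subtype=f["subtype"],
            probability=f["probability"],
            grade=f["grade"],
        )
        for f in payload["findings"]
    ]
    return CaseFinding(
        case_id=payload["case_id"],
        n_slices_evaluated=payload["n_slices_evaluated"],
        findings=findings,
    )
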