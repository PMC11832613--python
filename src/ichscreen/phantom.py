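"""Synthetic cranial CT phantoms with known ground truth.

Each phantom emulates the acquisition the screening protocol expects — an
axial head series, 4 mm slices, square matrix — as a geometric head: a
bone-density skull shell (+1000 HU) around soft-tissue parenchyma (35 HU)
with CSF-filled ventricles (5 HU) on the mid slices, over air background
(-1000 HU), plus additive Gaussian noise.  The intracranial radius tapers
hemispherically over the top third of slices, guaranteeing vertex slices
whose TIV area falls below the 0.4 upper-slice ratio.

Hyperdense lesions of the five hemorrhage subtypes are painted with
subtype-conventional shapes:

* IPH — ellipsoid (disc per slice) deep in parenchyma,
* IVH — ellipsoid inside the ventricle region,
* SAH — thin ribbon just under the inner skull surface,
* SDH — crescent hugging the inner skull over a long arc,
* EDH — biconvex lens at the skull over a short arc.

Streak artifacts (beam-hardening mimics, 80 HU) occupy exactly one vertex
slice so the adjacency-based suppression rule can remove them; artifact
voxels are never labeled as hemorrhage in the ground truth.  These phantoms
are deliberately simple: no CT physics, no anatomy — their job is to make
every pipeline rule testable with an exact oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .classifier import SUBTYPES
from .ct_io import CTVolume, write_dicom_series
from .errors import PhantomSpecError

__all__ = [
    "LesionSpec",
    "ArtifactSpec",
    "PhantomSpec",
    "GroundTruth",
    "default_radius_profile",
    "generate_phantom",
    "standard_lesion",
    "calibration_specs",
    "make_fixture_suite",
    "HU_AIR",
    "HU_PARENCHYMA",
    "HU_CSF",
    "HU_SKULL",
]

HU_AIR = -1000.0
HU_PARENCHYMA = 35.0
HU_CSF = 5.0
HU_SKULL = 1000.0
SKULL_THICKNESS_MM = 6.0

_SHAPE_FOR_SUBTYPE = {
    "IPH": "ellipsoid",
    "IVH": "ellipsoid",
    "SAH": "ribbon",
    "SDH": "crescent",
    "EDH": "lens",
}


@dataclass(frozen=True)
class LesionSpec:
    """One hemorrhage lesion.

    ``size_mm`` is the characteristic dimension: diameter for ellipsoids,
    maximum thickness for crescent/lens/ribbon.  ``angle_deg`` positions the
    lesion azimuthally; ``offset_mm`` is the radial center offset for
    ellipsoids; ``span_deg`` the angular extent of peripheral shapes.
    """

    subtype: str
    slice_range: tuple[int, int]  # inclusive
    shape: str
    mean_hu: float = 70.0
    size_mm: float = 16.0
    angle_deg: float = 0.0
    offset_mm: float = 0.0
    span_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise PhantomSpecError(f"unknown subtype {self.subtype!r}")
        if self.shape != _SHAPE_FOR_SUBTYPE[self.subtype]:
            raise PhantomSpecError(
                f"{self.subtype} lesions use shape {_SHAPE_FOR_SUBTYPE[self.subtype]!r},"
                f" got {self.shape!r}"
            )
        if self.slice_range[0] > self.slice_range[1]:
            raise PhantomSpecError("slice_range must be (low, high) inclusive")


@dataclass(frozen=True)
class ArtifactSpec:
    """A beam-hardening-style streak confined to exactly one vertex slice."""

    slice_index: int
    streak_hu: float = 80.0
    streak_width_mm: float = 3.0
    streak_length_mm: float = 18.0
    angle_deg: float = 30.0


@dataclass
class PhantomSpec:
    n_slices: int = 30
    matrix: int = 256
    pixel_spacing_mm: float = 0.9
    slice_thickness_mm: float = 4.0
    base_radius_mm: float = 75.0
    noise_sd_hu: float = 4.0
    head_radius_profile: Optional[np.ndarray] = None  # default: hemispherical taper
    lesions: list[LesionSpec] = field(default_factory=list)
    artifacts: list[ArtifactSpec] = field(default_factory=list)
    seed: int = 0

    def radius_profile(self) -> np.ndarray:
        if self.head_radius_profile is not None:
            profile = np.asarray(self.head_radius_profile, dtype=np.float64)
            if len(profile) != self.n_slices or not np.all(profile > 0):
                raise PhantomSpecError("radius profile must be positive, one value per slice")
            return profile
        return default_radius_profile(self.n_slices, self.base_radius_mm)

    def ventricle_slices(self) -> range:
        return range(int(0.25 * self.n_slices), int(0.60 * self.n_slices) + 1)


@dataclass
class GroundTruth:
    """Exact per-slice labels and masks implied by the phantom spec."""

    slice_labels: np.ndarray  # (n_slices, 5) bool, columns ordered as SUBTYPES
    tiv_mask_truth: np.ndarray  # (n_slices, rows, cols) bool

    @property
    def case_label(self) -> bool:
        return bool(self.slice_labels.any())


def default_radius_profile(
    n_slices: int, base_radius_mm: float = 75.0, min_radius_mm: float = 6.0
) -> np.ndarray:
    """Flat radius with a hemispherical-cap taper over the top third of slices."""
    n_taper = max(3, n_slices // 3)
    profile = np.full(n_slices, base_radius_mm)
    for k in range(1, n_taper + 1):
        frac = max(1.0 - (k / n_taper) ** 2, (min_radius_mm / base_radius_mm) ** 2)
        profile[n_slices - n_taper - 1 + k] = base_radius_mm * np.sqrt(frac)
    return profile


def _angdiff_deg(a: np.ndarray, b: float) -> np.ndarray:
    return np.abs((a - b + 180.0) % 360.0 - 180.0)


def _lesion_footprint(
    lesion: LesionSpec, r_slice: float, d: np.ndarray, ang: np.ndarray,
    xx: np.ndarray, yy: np.ndarray,
) -> np.ndarray:
    """Rasterize one lesion on one slice (pixel-center test, no antialiasing)."""
    if lesion.shape == "ellipsoid":
        radius = lesion.size_mm / 2.0
        if lesion.offset_mm + radius > r_slice - 1.0:
            raise PhantomSpecError(
                f"{lesion.subtype} lesion extends outside the intracranial region"
            )
        cx = lesion.offset_mm * np.cos(np.radians(lesion.angle_deg))
        cy = lesion.offset_mm * np.sin(np.radians(lesion.angle_deg))
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    if lesion.shape == "crescent":
        inner = r_slice - lesion.size_mm
        if inner <= 0:
            raise PhantomSpecError("crescent thicker than the intracranial radius")
        return (d >= inner) & (d <= r_slice) & (_angdiff_deg(ang, lesion.angle_deg) <= lesion.span_deg / 2)
    if lesion.shape == "lens":
        half = lesion.span_deg / 2.0
        delta = _angdiff_deg(ang, lesion.angle_deg)
        thickness = lesion.size_mm * np.clip(1.0 - (delta / half) ** 2, 0.0, 1.0)
        return (d <= r_slice) & (d >= r_slice - thickness) & (delta <= half)
    if lesion.shape == "ribbon":
        inset = 2.0
        outer = r_slice - inset
        inner = outer - lesion.size_mm
        if inner <= 0:
            raise PhantomSpecError("ribbon does not fit inside the intracranial region")
        return (d >= inner) & (d <= outer) & (_angdiff_deg(ang, lesion.angle_deg) <= lesion.span_deg / 2)
    raise PhantomSpecError(f"unknown lesion shape {lesion.shape!r}")


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Render a phantom volume and its exact ground truth; deterministic per seed."""
    profile = spec.radius_profile()
    m = spec.matrix
    sp = spec.pixel_spacing_mm
    coords = (np.arange(m) - (m - 1) / 2.0) * sp
    xx, yy = np.meshgrid(coords, coords)
    d = np.hypot(xx, yy)
    ang = np.degrees(np.arctan2(yy, xx))

    max_area_ratio = profile**2 / profile.max() ** 2

    volume = np.full((spec.n_slices, m, m), HU_AIR)
    tiv_truth = np.zeros((spec.n_slices, m, m), dtype=bool)
    labels = np.zeros((spec.n_slices, len(SUBTYPES)), dtype=bool)
    vent_slices = set(spec.ventricle_slices())

    for i in range(spec.n_slices):
        r = profile[i]
        inside = d <= r
        tiv_truth[i] = inside
        volume[i][inside] = HU_PARENCHYMA
        volume[i][(d > r) & (d <= r + SKULL_THICKNESS_MM)] = HU_SKULL
        if i in vent_slices and r >= 35.0:
            vent = (xx / 16.0) ** 2 + (yy / 10.0) ** 2 <= 1.0
            volume[i][vent & inside] = HU_CSF

    for lesion in spec.lesions:
        lo, hi = lesion.slice_range
        if lo < 0 or hi >= spec.n_slices:
            raise PhantomSpecError(f"lesion slice_range {lesion.slice_range} out of volume")
        if lesion.subtype == "IVH":
            for i in range(lo, hi + 1):
                if i not in vent_slices or profile[i] < 35.0:
                    raise PhantomSpecError(
                        f"IVH lesion on slice {i} requires the ventricle region"
                    )
        for i in range(lo, hi + 1):
            footprint = _lesion_footprint(lesion, profile[i], d, ang, xx, yy)
            if not footprint.any():
                raise PhantomSpecError(
                    f"{lesion.subtype} lesion footprint empty on slice {i}"
                )
            volume[i][footprint] = lesion.mean_hu
            labels[i, SUBTYPES.index(lesion.subtype)] = True

    for art in spec.artifacts:
        i = art.slice_index
        if not (0 <= i < spec.n_slices):
            raise PhantomSpecError(f"artifact slice {i} out of volume")
        if max_area_ratio[i] >= 0.4:
            raise PhantomSpecError(
                f"artifact slice {i} is not a vertex slice (area ratio "
                f"{max_area_ratio[i]:.2f} >= 0.4)"
            )
        half_len = art.streak_length_mm / 2.0
        if half_len + 2.0 > profile[i]:
            raise PhantomSpecError("streak does not fit inside the vertex slice")
        theta = np.radians(art.angle_deg)
        along = xx * np.cos(theta) + yy * np.sin(theta)
        across = -xx * np.sin(theta) + yy * np.cos(theta)
        streak = (np.abs(along) <= half_len) & (np.abs(across) <= art.streak_width_mm / 2.0)
        volume[i][streak] = art.streak_hu  # NOT added to the hemorrhage labels

    rng = np.random.default_rng(spec.seed)
    volume = volume + rng.normal(0.0, spec.noise_sd_hu, size=volume.shape)

    ct = CTVolume(
        slices=volume,
        pixel_spacing=(sp, sp),
        slice_thickness=spec.slice_thickness_mm,
        slice_positions=np.arange(spec.n_slices) * spec.slice_thickness_mm,
        series_id="",
    )
    return ct, GroundTruth(slice_labels=labels, tiv_mask_truth=tiv_truth)


# --------------------------------------------------------------------------
# Fixture suite
# --------------------------------------------------------------------------


def standard_lesion(subtype: str, lo: int, hi: int, **kw) -> LesionSpec:
    """A lesion of the given subtype with the suite's conventional geometry."""
    defaults: dict = {
        "IPH": dict(shape="ellipsoid", mean_hu=70.0, size_mm=16.0, offset_mm=35.0),
        "IVH": dict(shape="ellipsoid", mean_hu=65.0, size_mm=10.0),
        "SAH": dict(shape="ribbon", mean_hu=60.0, size_mm=3.0, span_deg=60.0, angle_deg=45.0),
        "SDH": dict(shape="crescent", mean_hu=75.0, size_mm=10.0, span_deg=120.0, angle_deg=180.0),
        "EDH": dict(shape="lens", mean_hu=65.0, size_mm=12.0, span_deg=44.0, angle_deg=90.0),
    }[subtype]
    defaults.update(kw)
    return LesionSpec(subtype=subtype, slice_range=(lo, hi), **defaults)


def calibration_specs(seed: int = 0) -> list[PhantomSpec]:
    """A small labeled phantom set for threshold calibration: one phantom per
    subtype plus a clean negative (every label sees both classes)."""
    specs = [PhantomSpec(seed=seed)]
    ranges = {"IPH": (10, 12), "IVH": (12, 14), "SAH": (9, 11), "SDH": (8, 13), "EDH": (9, 12)}
    for k, subtype in enumerate(SUBTYPES, start=1):
        lo, hi = ranges[subtype]
        specs.append(
            PhantomSpec(lesions=[standard_lesion(subtype, lo, hi)], seed=seed + 100 + k)
        )
    return specs


def _suite_specs(seed: int) -> list[tuple[str, PhantomSpec, dict]]:
    """The standard named phantom cases with their expected end-to-end verdicts."""
    upper = 27  # first slice whose TIV ratio falls below 0.4 in the default profile
    lesion = standard_lesion

    cases: list[tuple[str, PhantomSpec, dict]] = []

    def add(name, spec, positive, dominant=None, subtypes=(), **extra):
        expected = {
            "valid": extra.pop("valid", True),
            "positive": positive,
            "dominant_subtype": dominant,
            "subtypes": sorted(subtypes),
        }
        expected.update(extra)
        cases.append((name, spec, expected))

    base = dict(seed=seed)
    add("clean_negative", PhantomSpec(**base), False)
    add("iph", PhantomSpec(lesions=[lesion("IPH", 10, 12)], seed=seed + 1), True, "IPH", ["IPH"])
    add("ivh", PhantomSpec(lesions=[lesion("IVH", 12, 14)], seed=seed + 2), True, "IVH", ["IVH"])
    add("sah", PhantomSpec(lesions=[lesion("SAH", 9, 11)], seed=seed + 3), True, "SAH", ["SAH"])
    add("sdh", PhantomSpec(lesions=[lesion("SDH", 8, 13)], seed=seed + 4), True, "SDH", ["SDH"])
    add("edh", PhantomSpec(lesions=[lesion("EDH", 9, 12)], seed=seed + 5), True, "EDH", ["EDH"])
    add(
        "multi_subtype",
        PhantomSpec(lesions=[lesion("IPH", 10, 12), lesion("SDH", 8, 13)], seed=seed + 6),
        True,
        "SDH",
        ["IPH", "SDH"],
    )
    add(
        "artifact_only",
        PhantomSpec(artifacts=[ArtifactSpec(slice_index=upper + 1)], seed=seed + 7),
        False,
        positive_without_postprocessing=True,
    )
    add(
        "artifact_plus_lesion",
        PhantomSpec(
            lesions=[lesion("IPH", 10, 12)],
            artifacts=[ArtifactSpec(slice_index=upper + 1)],
            seed=seed + 8,
        ),
        True,
        "IPH",
        ["IPH"],
    )
    add(
        "vertex_pair_lesion",
        PhantomSpec(lesions=[lesion("SDH", upper, upper + 1)], seed=seed + 9),
        True,
        "SDH",
        ["SDH"],
    )
    add(
        "too_few_slices",
        PhantomSpec(n_slices=12, seed=seed + 10),
        False,
        valid=False,
    )
    return cases


def make_fixture_suite(out_dir, seed: int = 7) -> dict:
    """Write the standard phantom suite as DICOM series plus truth and manifest.

    Returns the manifest dict; also written as ``manifest.json`` in
    ``out_dir``.  Per case: a DICOM series directory and a truth CSV
    (slice_index, subtype, label).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "cases": []}
    for name, spec, expected in _suite_specs(seed):
        volume, truth = generate_phantom(spec)
        case_dir = out_dir / name
        write_dicom_series(volume, case_dir)
        rows = [
            {"slice_index": i, "subtype": s, "label": int(truth.slice_labels[i, j])}
            for i in range(spec.n_slices)
            for j, s in enumerate(SUBTYPES)
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"{name}_truth.csv", index=False)
        manifest["cases"].append(
            {"case_id": name, "dicom_dir": name, "expected": expected}
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
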