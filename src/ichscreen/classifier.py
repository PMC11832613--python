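"""Slice-level hemorrhage classification: contract, calibration, references.

The classifier contract is narrow: map a tri-window slice image plus
per-case context masks to six probabilities in [0, 1] — one per hemorrhage
subtype (IPH, IVH, SAH, SDH, EDH) and an "Any" head indicating hemorrhage of
some kind on the slice.  The six outputs are independent sigmoid-style
scores, not a softmax: subtypes co-occur.

Two reference implementations honor the contract:

* :class:`HeuristicSliceClassifier` — a deterministic intensity heuristic
  for desk-scale testing.  It recovers approximate HU from the subdural
  channel, scores the smoothed fraction of intracranial pixels in the acute
  blood band (50–90 HU) through a fixed logistic, and apportions subtype
  probabilities by lesion geometry (ventricle overlap, distance to the
  intracranial rim, component thickness, angular span along the skull).
* :func:`fit_small_model` — an optional trainable hook: six independent
  logistic regressions over summary image features, minimizing per-label
  binary cross-entropy.  Desk-scale only; not the production path.

Decision thresholds are calibrated per label by maximizing sensitivity +
specificity over the ROC curve (Youden-style); a slice is positive for a
subtype only when both that subtype's score and the "Any" score exceed
their thresholds (strictly).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Optional, Protocol

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import CalibrationError, GeometryError, ParameterError
from .windowing import SUBDURAL_WINDOW, TriWindowImage, WindowSpec

__all__ = [
    "SUBTYPES",
    "SubtypeProbabilities",
    "ThresholdSet",
    "LabeledScoreSet",
    "SliceContext",
    "SliceClassifier",
    "HeuristicSliceClassifier",
    "calibrate_threshold",
    "binarize",
    "fit_small_model",
    "SmallTrainedClassifier",
]

SUBTYPES = ("IPH", "IVH", "SAH", "SDH", "EDH")
_LABELS = SUBTYPES + ("Any",)


@dataclass(frozen=True)
class SubtypeProbabilities:
    """Per-slice scores for the five subtypes plus the "Any" head."""

    slice_index: int
    p_iph: float
    p_ivh: float
    p_sah: float
    p_sdh: float
    p_edh: float
    p_any: float

    def __post_init__(self) -> None:
        for name, p in self.as_dict().items():
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"probability {name}={p} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {
            "IPH": self.p_iph,
            "IVH": self.p_ivh,
            "SAH": self.p_sah,
            "SDH": self.p_sdh,
            "EDH": self.p_edh,
            "Any": self.p_any,
        }


@dataclass(frozen=True)
class ThresholdSet:
    """Calibrated decision thresholds, one per label."""

    theta_iph: float = 0.5
    theta_ivh: float = 0.5
    theta_sah: float = 0.5
    theta_sdh: float = 0.5
    theta_edh: float = 0.5
    theta_any: float = 0.5

    def __post_init__(self) -> None:
        for name, t in self.as_dict().items():
            if not (0.0 <= t <= 1.0):
                raise ParameterError(f"threshold {name}={t} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {
            "IPH": self.theta_iph,
            "IVH": self.theta_ivh,
            "SAH": self.theta_sah,
            "SDH": self.theta_sdh,
            "EDH": self.theta_edh,
            "Any": self.theta_any,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ThresholdSet":
        return cls(
            theta_iph=d["IPH"],
            theta_ivh=d["IVH"],
            theta_sah=d["SAH"],
            theta_sdh=d["SDH"],
            theta_edh=d["EDH"],
            theta_any=d["Any"],
        )


@dataclass
class LabeledScoreSet:
    """Scores with binary ground-truth labels; the calibration input."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ParameterError("scores and labels must be 1-D of equal length")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ParameterError("labels must be binary")


@dataclass
class SliceContext:
    """Per-slice context masks aligned to the image: intracranial (TIV) mask,
    optional ventricle map, and the pixel spacing in mm."""

    tiv_mask: np.ndarray
    pixel_spacing: tuple[float, float]
    ventricle_mask: Optional[np.ndarray] = None


class SliceClassifier(Protocol):
    """Plugin contract: deterministic map (image, context) -> probabilities."""

    def classify(self, image: TriWindowImage, context: SliceContext) -> SubtypeProbabilities: ...


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def _angular_span_deg(rows: np.ndarray, cols: np.ndarray, center: tuple[float, float]) -> float:
    """Circular range (degrees) of component pixels around a center point."""
    ang = np.degrees(np.arctan2(rows - center[0], cols - center[1]))
    ang = np.sort(ang)
    if len(ang) < 2:
        return 0.0
    gaps = np.diff(ang)
    wrap_gap = 360.0 - (ang[-1] - ang[0])
    return 360.0 - max(float(gaps.max(initial=0.0)), wrap_gap)


@dataclass
class HeuristicSliceClassifier:
    """Deterministic intensity-and-geometry reference classifier.

    Evidence score: gaussian-smooth the HU estimate recovered from the
    subdural channel, take the fraction of intra-TIV pixels inside the blood
    band, and map it through ``logistic((frac - midpoint)/scale)``.  Subtype
    scores apportion the same evidence by the geometry of each blood-band
    connected component:

    * majority overlap with the ventricle map → IVH;
    * deep to the intracranial rim (median edge distance > ``rim_mm``) → IPH;
    * peripheral and thin (< ``thin_mm``) → SAH;
    * peripheral, thick, long arc (> ``sdh_span_deg``) → SDH, short arc → EDH.

    The band bounds and logistic constants are fixture parameters of this
    reference implementation, not claims about any production network.
    """

    blood_hu_low: float = 50.0
    blood_hu_high: float = 90.0
    smooth_sigma_px: float = 1.0
    rim_exclusion_px: Optional[int] = None  # default: ceil(3 * smooth_sigma_px)
    logistic_midpoint: float = 0.002
    logistic_scale: float = 0.0008
    rim_mm: float = 8.0
    thin_mm: float = 4.5
    sdh_span_deg: float = 70.0
    subdural_window: WindowSpec = field(default=SUBDURAL_WINDOW)

    def classify(self, image: TriWindowImage, context: SliceContext) -> SubtypeProbabilities:
        tiv = np.asarray(context.tiv_mask, dtype=bool)
        sub = image.channels[:, :, 1]
        if sub.shape != tiv.shape:
            raise GeometryError(
                f"image shape {sub.shape} does not match TIV mask shape {tiv.shape}"
            )
        w = self.subdural_window
        # invert the subdural window where unclipped; clipped pixels land on
        # the window edges, outside the blood band for any standard setup
        hu_est = sub * w.width + w.lower
        hu_smooth = ndimage.gaussian_filter(hu_est, sigma=self.smooth_sigma_px)
        # smoothing drags skull-adjacent pixels through the blood band, so a
        # 3-sigma rim along the mask edge is excluded from the evidence
        erode = (
            self.rim_exclusion_px
            if self.rim_exclusion_px is not None
            else int(np.ceil(3.0 * self.smooth_sigma_px))
        )
        if erode > 0 and tiv.any():
            tiv = ndimage.binary_erosion(tiv, iterations=erode)
        blood = (
            (hu_smooth >= self.blood_hu_low)
            & (hu_smooth <= self.blood_hu_high)
            & tiv
        )

        n_tiv = int(tiv.sum())
        frac_by_label = {name: 0.0 for name in _LABELS}
        if n_tiv > 0 and blood.any():
            frac_by_label["Any"] = float(blood.sum()) / n_tiv
            self._apportion(blood, tiv, context, frac_by_label)

        def p(name: str) -> float:
            return float(
                _logistic((frac_by_label[name] - self.logistic_midpoint) / self.logistic_scale)
            )

        return SubtypeProbabilities(
            slice_index=image.source_slice_index,
            p_iph=p("IPH"),
            p_ivh=p("IVH"),
            p_sah=p("SAH"),
            p_sdh=p("SDH"),
            p_edh=p("EDH"),
            p_any=p("Any"),
        )

    def _apportion(
        self,
        blood: np.ndarray,
        tiv: np.ndarray,
        context: SliceContext,
        frac_by_label: dict[str, float],
    ) -> None:
        spacing = context.pixel_spacing
        n_tiv = int(tiv.sum())
        edge_dist = ndimage.distance_transform_edt(tiv, sampling=spacing)
        center = ndimage.center_of_mass(tiv)
        vent = (
            np.asarray(context.ventricle_mask, dtype=bool)
            if context.ventricle_mask is not None
            else None
        )

        labeled = measure.label(blood, connectivity=2)
        for region_label in range(1, labeled.max() + 1):
            comp = labeled == region_label
            subtype = self._component_subtype(comp, edge_dist, center, vent, spacing)
            frac_by_label[subtype] += float(comp.sum()) / n_tiv

    def _component_subtype(
        self,
        comp: np.ndarray,
        edge_dist: np.ndarray,
        center: tuple[float, float],
        vent: Optional[np.ndarray],
        spacing: tuple[float, float],
    ) -> str:
        if vent is not None and vent.any():
            overlap = float((comp & vent).sum()) / float(comp.sum())
            if overlap > 0.5:
                return "IVH"
        if float(np.median(edge_dist[comp])) > self.rim_mm:
            return "IPH"
        # peripheral collection: thickness = 2 * inradius of the component
        thickness = 2.0 * float(
            ndimage.distance_transform_edt(comp, sampling=spacing).max()
        )
        if thickness < self.thin_mm:
            return "SAH"
        rows, cols = np.nonzero(comp)
        span = _angular_span_deg(rows.astype(float), cols.astype(float), center)
        return "SDH" if span > self.sdh_span_deg else "EDH"


def calibrate_threshold(data: LabeledScoreSet) -> float:
    """Youden-style threshold: maximize SEN(θ) + SPEC(θ) with strict-> positivity.

    Candidate cuts are 0 plus the distinct score values — with the strict
    "above" rule these realize every achievable classification, and each at
    its smallest θ.  Among maximizers the smallest θ is returned, favoring
    sensitivity.
    """
    scores, labels = data.scores, data.labels
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("calibration requires at least one positive and one negative")

    candidates = np.unique(np.concatenate(([0.0], scores)))
    best_theta, best_j = None, -np.inf
    for theta in candidates:
        pred = scores > theta
        sen = float((pred & (labels == 1)).sum()) / n_pos
        spec = float((~pred & (labels == 0)).sum()) / n_neg
        j = sen + spec
        if j > best_j + 1e-12:  # strict improvement keeps the smallest maximizer
            best_j, best_theta = j, float(theta)
    return best_theta


def binarize(probs: SubtypeProbabilities, thresholds: ThresholdSet) -> dict[str, bool]:
    """Per-subtype slice detection: p_t > θ_t AND p_any > θ_any (both strict)."""
    p = probs.as_dict()
    t = thresholds.as_dict()
    any_gate = p["Any"] > t["Any"]
    return {s: bool(any_gate and p[s] > t[s]) for s in SUBTYPES}


# --------------------------------------------------------------------------
# Optional small trainable hook (desk scale; not the production path)
# --------------------------------------------------------------------------


def _image_features(image: TriWindowImage) -> np.ndarray:
    """Deterministic summary features of a tri-window slice."""
    ch = image.channels
    sub = ch[:, :, 1]
    w = SUBDURAL_WINDOW
    hu = sub * w.width + w.lower
    blood = (hu >= 50.0) & (hu <= 90.0)
    feats = [
        ch[:, :, 0].mean(), ch[:, :, 0].std(),
        ch[:, :, 1].mean(), ch[:, :, 1].std(),
        ch[:, :, 2].mean(), ch[:, :, 2].std(),
        blood.mean(),
        float(np.percentile(sub, 99)),
    ]
    return np.array(feats, dtype=np.float64)


@dataclass
class SmallTrainedClassifier:
    """Six independent logistic models over summary features.

    Honors the slice-classifier contract; the context masks are accepted but
    unused (the features are image-global).  Desk-scale demonstrator only.
    """

    models: dict
    feature_means: np.ndarray
    feature_stds: np.ndarray

    def classify(self, image: TriWindowImage, context: SliceContext) -> SubtypeProbabilities:
        x = (_image_features(image) - self.feature_means) / self.feature_stds
        p = {}
        for name in _LABELS:
            model = self.models[name]
            if model is None:  # label constant in training: emit its constant rate
                p[name] = self.models[f"{name}__rate"]
            else:
                p[name] = float(model.predict_proba(x.reshape(1, -1))[0, 1])
        return SubtypeProbabilities(
            slice_index=image.source_slice_index,
            p_iph=p["IPH"], p_ivh=p["IVH"], p_sah=p["SAH"],
            p_sdh=p["SDH"], p_edh=p["EDH"], p_any=p["Any"],
        )

    def to_bytes(self) -> bytes:
        return pickle.dumps(self, protocol=4)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "SmallTrainedClassifier":
        obj = pickle.loads(blob)
        if not isinstance(obj, cls):
            raise ParameterError("blob does not contain a SmallTrainedClassifier")
        return obj


def fit_small_model(
    labeled_images: list[tuple[TriWindowImage, dict[str, int]]],
    epochs: int = 100,
    seed: int = 0,
) -> SmallTrainedClassifier:
    """Fit the small per-label logistic classifier on labeled slices.

    Each training item is ``(image, labels)`` with labels keyed by
    IPH/IVH/SAH/SDH/EDH/Any.  Minimizes per-label binary cross-entropy;
    deterministic given ``seed``.  Raises on an empty set or when the "Any"
    label is single-class.
    """
    from sklearn.linear_model import LogisticRegression

    if not labeled_images:
        raise CalibrationError("empty training set")
    X = np.stack([_image_features(img) for img, _ in labeled_images])
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    stds[stds == 0] = 1.0
    Xn = (X - means) / stds

    y_any = np.array([labels.get("Any", 0) for _, labels in labeled_images])
    if len(np.unique(y_any)) < 2:
        raise CalibrationError("training data must contain both classes for 'Any'")

    models: dict = {}
    for name in _LABELS:
        y = np.array([labels.get(name, 0) for _, labels in labeled_images])
        if len(np.unique(y)) < 2:
            models[name] = None
            models[f"{name}__rate"] = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
            continue
        model = LogisticRegression(max_iter=max(epochs, 100), random_state=seed)
        model.fit(Xn, y)
        models[name] = model
    return SmallTrainedClassifier(models=models, feature_means=means, feature_stds=stds)
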