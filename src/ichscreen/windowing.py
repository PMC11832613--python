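"""CT display windowing and the three-window slice composition.

A CT display window maps Hounsfield units to gray values: values inside
``[WL - WW/2, WL + WW/2]`` span the visible range linearly, values outside
clip.  The classifier input stacks three standard head windows — brain
(WL 30, WW 80), subdural (WL 80, WW 200) and bone (WL 600, WW 2800) — into
one RGB-like image, so soft tissue, thin peri-osseous collections and bone
are each rendered at a contrast a radiologist would use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import ParameterError

__all__ = [
    "WindowSpec",
    "TriWindowImage",
    "BRAIN_WINDOW",
    "SUBDURAL_WINDOW",
    "BONE_WINDOW",
    "DEFAULT_WINDOWS",
    "apply_window",
    "compose_tri_window",
    "export_composite_png",
]


@dataclass(frozen=True)
class WindowSpec:
    """A display window: center ``level`` (WL) and full ``width`` (WW), in HU."""

    level: float
    width: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ParameterError(f"window width must be > 0, got {self.width}")

    @property
    def lower(self) -> float:
        return self.level - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.level + self.width / 2.0


BRAIN_WINDOW = WindowSpec(level=30.0, width=80.0, name="brain")
SUBDURAL_WINDOW = WindowSpec(level=80.0, width=200.0, name="subdural")
BONE_WINDOW = WindowSpec(level=600.0, width=2800.0, name="bone")
DEFAULT_WINDOWS = (BRAIN_WINDOW, SUBDURAL_WINDOW, BONE_WINDOW)


@dataclass(frozen=True)
class TriWindowImage:
    """Three-channel windowed slice, channels in [0, 1], order brain/subdural/bone.

    ``channels`` has shape ``(rows, cols, 3)``; ``windows`` records the specs
    the channels were rendered with so downstream consumers can invert the
    (unclipped part of the) mapping back to HU.
    """

    channels: np.ndarray
    source_slice_index: int
    windows: tuple[WindowSpec, WindowSpec, WindowSpec] = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[2] != 3:
            raise ParameterError(
                f"channels must have shape (rows, cols, 3), got {self.channels.shape}"
            )


def apply_window(slice_hu: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Map HU values through a display window onto [0, 1].

    ``v`` maps to ``clip((v - (WL - WW/2)) / WW, 0, 1)``: monotone, linear
    inside the window, clipped at both edges.
    """
    if not window.width > 0:  # defensive: WindowSpec already enforces this
        raise ParameterError("window width must be positive")
    hu = np.asarray(slice_hu, dtype=np.float64)
    return np.clip((hu - window.lower) / window.width, 0.0, 1.0)


def compose_tri_window(
    slice_hu: np.ndarray,
    specs: tuple[WindowSpec, ...] = DEFAULT_WINDOWS,
    slice_index: int = 0,
) -> TriWindowImage:
    """Stack three windowed renderings of one slice into a TriWindowImage."""
    if len(specs) != 3:
        raise ParameterError(f"exactly 3 window specs required, got {len(specs)}")
    channels = np.stack([apply_window(slice_hu, w) for w in specs], axis=-1)
    return TriWindowImage(
        channels=channels, source_slice_index=slice_index, windows=tuple(specs)
    )


def export_composite_png(image: TriWindowImage, path) -> str:
    """Write the composition as an 8-bit RGB PNG; channel value v stores round(255 v)."""
    # np.rint rounds half-to-even; the stated convention is half-up.
    bytes_img = np.floor(image.channels * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(bytes_img, mode="RGB").save(path, format="PNG")
    return str(path)
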