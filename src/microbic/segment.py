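"""Windowed tri-class thresholding of longitudinal slices.

A pixel is IMPLANT if its intensity reaches the metal threshold, BONE if it
falls inside the inclusive bone window, and BACKGROUND otherwise (air, soft
tissue, and the no-man's-land between the bone window and the metal
threshold all map to the single background class).  The default bone window
[60, 90] on the 8-bit scale is the histology-calibrated window for newly
formed bone; the metal threshold (default 200) merely needs to sit well
above the bone window since titanium is far brighter.

An optional speckle filter removes connected bone components (8-connectivity)
below a minimum pixel count; an optional 3x3 median prefilter is available
but off by default — the faithful pipeline thresholds the raw grayscale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import LABEL_BACKGROUND, LABEL_BONE, LABEL_IMPLANT, LabelImage, SliceImage

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationConfig:
    bone_min: float = 60.0
    bone_max: float = 90.0
    implant_min: float = 200.0
    min_component_px: int = 0
    median_prefilter: bool = False

    def __post_init__(self) -> None:
        if not (self.bone_min <= self.bone_max < self.implant_min):
            raise ValueError(
                f"thresholds must satisfy bone_min <= bone_max < implant_min, got "
                f"({self.bone_min}, {self.bone_max}, {self.implant_min})"
            )
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")


def classify(s: SliceImage, cfg: SegmentationConfig | None = None) -> LabelImage:
    """Convert a grayscale slice to the tri-class halftone label image."""
    cfg = cfg or SegmentationConfig()
    px = np.asarray(s.pixels, dtype=np.float32)
    if cfg.median_prefilter:
        px = ndimage.median_filter(px, size=3)
    labels = np.full(px.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[(px >= cfg.bone_min) & (px <= cfg.bone_max)] = LABEL_BONE
    labels[px >= cfg.implant_min] = LABEL_IMPLANT
    if cfg.min_component_px > 0:
        labels = _despeckle_bone(labels, cfg.min_component_px)
    return LabelImage(
        labels=labels,
        pixel_size_um=s.pixel_size_um,
        angle_deg=s.angle_deg,
        origin=s.origin,
        basis=s.basis,
    )


def _despeckle_bone(labels: np.ndarray, min_px: int) -> np.ndarray:
    comp, n = ndimage.label(labels == LABEL_BONE, structure=_EIGHT)
    if n == 0:
        return labels
    sizes = np.bincount(comp.ravel())
    small = sizes < min_px
    small[0] = False
    out = labels.copy()
    out[small[comp]] = LABEL_BACKGROUND
    return out
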