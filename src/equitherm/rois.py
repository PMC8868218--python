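"""Regions of interest over the imaged thoracolumbar area.

Four ROIs follow the segmentation used for conventional equine
thermography of the back: ROI 1 the withers, ROI 2 the thoracic spine,
ROI 3 and ROI 4 the left and right back-muscle areas.  Masks are stored
as boolean rasters sharing the image dimensions and serialized as a
single-channel label raster with values 1-4 (0 = background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ROI_LABELS = (1, 2, 3, 4)
ROI_NAMES = {1: "withers", 2: "thoracic_spine", 3: "left_muscles", 4: "right_muscles"}
#: ROIs overlying working muscle, where post-exercise warming concentrates.
MUSCLE_ROIS = (1, 3, 4)

# Rectangular extents as (row0, row1, col0, col1) fractions of the frame.
_LAYOUT = {
    1: (0.15, 0.45, 0.05, 0.25),
    2: (0.42, 0.58, 0.30, 0.95),
    3: (0.15, 0.38, 0.30, 0.92),
    4: (0.62, 0.85, 0.30, 0.92),
}


@dataclass(frozen=True)
class ROISet:
    """Four labeled binary masks with shared raster dimensions."""

    masks: dict  # label -> bool ndarray (H, W)

    def __post_init__(self) -> None:
        if set(self.masks) != set(ROI_LABELS):
            raise ValueError(f"ROI labels must be {ROI_LABELS}, got {sorted(self.masks)}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("ROI masks must share raster dimensions")
        for label, m in self.masks.items():
            if not m.any():
                raise ValueError(f"ROI {label} mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def __getitem__(self, label: int) -> np.ndarray:
        return self.masks[label]

    def items(self):
        return sorted(self.masks.items())

    def labels_raster(self) -> np.ndarray:
        """Single-channel label raster, 0 = background."""
        out = np.zeros(self.shape, dtype=np.uint8)
        for label, m in self.items():
            out[m] = label
        return out

    @classmethod
    def from_labels(cls, raster: np.ndarray, source: str = "<raster>") -> "ROISet":
        raster = np.asarray(raster)
        bad = sorted(int(v) for v in set(np.unique(raster)) - {0, 1, 2, 3, 4})
        if bad:
            raise ValueError(
                f"{source}: mask raster contains invalid label(s) {bad}; "
                "expected labels in {0, 1, 2, 3, 4}"
            )
        return cls({label: raster == label for label in ROI_LABELS})

    def bbox(self, label: int) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1), half-open, of the mask's extent."""
        rows = np.flatnonzero(self.masks[label].any(axis=1))
        cols = np.flatnonzero(self.masks[label].any(axis=0))
        return rows[0], rows[-1] + 1, cols[0], cols[-1] + 1


def default_roi_set(height: int, width: int) -> ROISet:
    """Deterministic rectangular ROI layout scaled to the frame size."""
    if height < 8 or width < 8:
        raise ValueError("frame too small for the four-ROI layout")
    masks = {}
    for label, (r0, r1, c0, c1) in _LAYOUT.items():
        m = np.zeros((height, width), dtype=bool)
        m[int(r0 * height): int(r1 * height), int(c0 * width): int(c1 * width)] = True
        masks[label] = m
    return ROISet(masks)
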