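"""Color-model decomposition and gray-level normalization.

A pseudo-color thermogram is decomposed into the 12 components of four
color models — RGB (R, G, B), YUV (Y, U, V), YIQ (Y, I, Q) and HSB
(H, S, B) — each yielding one gray channel for texture analysis.  YUV and
YIQ use the BT.601 luma weights and standard chrominance matrices; HSB is
the hexcone model with B = max(R, G, B).  Signed chrominance planes are
mapped affinely so the achromatic value sits at the center of the 8-bit
gray range, and hue is linearized from [0, 360) onto the gray range.

Each component is analyzed both un-normalized (capital letter: R, Y, ...)
and after ROI-based gray-level normalization (lowercase: r, y, ...),
giving 24 channel variants per image.  Normalization remaps gray levels
onto [1, 2^n] from ROI-derived bounds:

    I_out = clamp(round(2^n * (I_in - MIN) / (MAX - MIN)) + 1, 1, 2^n)

with bounds MIN/MAX taken as mean +/- 3 SD, min/max, or the 1st/99th
percentiles of the ROI gray levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

logger = logging.getLogger(__name__)

#: (model, component) pairs in enumeration order; 12 components total.
COMPONENTS = (
    ("RGB", "R"), ("RGB", "G"), ("RGB", "B"),
    ("YUV", "Y"), ("YUV", "U"), ("YUV", "V"),
    ("YIQ", "Y"), ("YIQ", "I"), ("YIQ", "Q"),
    ("HSB", "H"), ("HSB", "S"), ("HSB", "B"),
)

NORMALIZATION_KINDS = ("none", "mu3sigma", "minmax", "perc1_99")

# BT.601 chrominance coefficient rows (applied to R, G, B in [0, 255]).
_CHROMA = {
    "U": (-0.14713, -0.28886, 0.436),
    "V": (0.615, -0.51499, -0.10001),
    "I": (0.595716, -0.274453, -0.321263),
    "Q": (0.211456, -0.522591, 0.311135),
}


def decompose(image: np.ndarray) -> dict:
    """Decompose an 8-bit RGB image into 12 gray planes scaled to [0, 255].

    Returns ``{(model, component): float plane}`` keyed like
    :data:`COMPONENTS`.  The Y plane is shared between YUV and YIQ but
    enumerated under both models.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    r = img[..., 0].astype(float)
    g = img[..., 1].astype(float)
    b = img[..., 2].astype(float)

    y = 0.299 * r + 0.587 * g + 0.114 * b
    planes = {("RGB", "R"): r, ("RGB", "G"): g, ("RGB", "B"): b}
    for model, comp in (("YUV", "Y"), ("YIQ", "Y")):
        planes[(model, comp)] = y
    for comp, (cr, cg, cb) in _CHROMA.items():
        raw = cr * r + cg * g + cb * b
        # coefficient rows are balanced, so the attainable range is
        # symmetric about 0; center the achromatic value on mid-gray
        pos = sum(c for c in (cr, cg, cb) if c > 0) * 255.0
        gray = raw * (255.0 / (2.0 * pos)) + 127.5
        model = "YUV" if comp in ("U", "V") else "YIQ"
        planes[(model, comp)] = gray

    hsv = rgb2hsv(img.astype(np.uint8))
    planes[("HSB", "H")] = hsv[..., 0] * 255.0   # hue angle linearized
    planes[("HSB", "S")] = hsv[..., 1] * 255.0
    planes[("HSB", "B")] = hsv[..., 2] * 255.0   # max(R, G, B)
    return planes


@dataclass
class NormalizationScheme:
    """Gray-level normalization onto [1, 2^n] from ROI-derived bounds."""

    kind: str = "minmax"
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.kind not in NORMALIZATION_KINDS:
            raise ValueError(
                f"unknown normalization {self.kind!r}; expected one of "
                f"{NORMALIZATION_KINDS}"
            )

    def bounds(self, plane: np.ndarray, roi: np.ndarray) -> tuple[float, float]:
        vals = np.asarray(plane, dtype=float)[np.asarray(roi, dtype=bool)]
        if vals.size == 0:
            raise ValueError("ROI is empty; cannot derive normalization bounds")
        if self.kind == "none":
            return 0.0, float(2**self.bit_depth)
        if self.kind == "mu3sigma":
            mu, sigma = vals.mean(), vals.std()
            return mu - 3 * sigma, mu + 3 * sigma
        if self.kind == "minmax":
            return float(vals.min()), float(vals.max())
        p1, p99 = np.percentile(vals, [1, 99])
        return float(p1), float(p99)


@dataclass
class ChannelImage:
    """One gray-level plane ready for texture extraction.

    ``data`` holds integers in [1, 2^bit_depth]; ``label`` is the field's
    channel annotation (capital letter un-normalized, lowercase
    normalized), qualified by the color model.
    """

    model: str
    component: str
    normalized: bool
    normalization: str
    data: np.ndarray
    bit_depth: int
    degenerate: bool = False

    @property
    def letter(self) -> str:
        return self.component.lower() if self.normalized else self.component

    @property
    def label(self) -> str:
        return f"{self.model}.{self.letter}"

    @property
    def n_levels(self) -> int:
        return 2**self.bit_depth


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def normalize(
    plane: np.ndarray,
    scheme: NormalizationScheme,
    roi: np.ndarray,
) -> tuple[np.ndarray, bool]:
    """Map a float plane onto integer gray levels [1, 2^n].

    Returns ``(data, degenerate)``.  ``kind='none'`` shifts 8-bit gray
    levels to [1, 256] without rescaling; the other kinds clip to the
    ROI-derived [MIN, MAX] and rescale.  A degenerate range (constant
    plane under minmax) yields an all-1 plane and ``degenerate=True``.
    """
    plane = np.asarray(plane, dtype=float)
    n = scheme.bit_depth
    if scheme.kind == "none":
        data = np.clip(_round_half_up(plane), 0, 2**n - 1).astype(np.int32) + 1
        return data, False
    lo, hi = scheme.bounds(plane, roi)
    if not hi > lo:
        logger.warning(
            "degenerate normalization range [%.6g, %.6g]; output all-1", lo, hi
        )
        return np.ones(plane.shape, dtype=np.int32), True
    clipped = np.clip(plane, lo, hi)
    scaled = _round_half_up(2**n * (clipped - lo) / (hi - lo)) + 1
    return np.clip(scaled, 1, 2**n).astype(np.int32), False


def requantize(data: np.ndarray, from_bits: int, to_bits: int) -> np.ndarray:
    """Uniformly rebin gray levels [1, 2^from] onto [1, 2^to]."""
    if to_bits > from_bits:
        raise ValueError("cannot requantize upward")
    if to_bits == from_bits:
        return data
    shift = 2 ** (from_bits - to_bits)
    return (data - 1) // shift + 1


def channel_variants(
    image: np.ndarray,
    roi: np.ndarray,
    normalized_variant: str = "minmax",
    bit_depth: int = 8,
) -> list:
    """The 24 channel variants of one image for one ROI.

    Each of the 12 color components appears un-normalized and normalized
    (bounds from the ROI pixels), in enumeration order.
    """
    planes = decompose(image)
    none_scheme = NormalizationScheme("none", bit_depth)
    norm_scheme = NormalizationScheme(normalized_variant, bit_depth)
    variants = []
    for model, comp in COMPONENTS:
        plane = planes[(model, comp)]
        for normalized, scheme in ((False, none_scheme), (True, norm_scheme)):
            data, degenerate = normalize(plane, scheme, roi)
            variants.append(
                ChannelImage(
                    model=model,
                    component=comp,
                    normalized=normalized,
                    normalization=scheme.kind,
                    data=data,
                    bit_depth=bit_depth,
                    degenerate=degenerate,
                )
            )
    return variants
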