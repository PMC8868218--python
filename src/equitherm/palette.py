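"""Rainbow palette mapping between surface temperature and pseudo-color RGB.

Thermal cameras render the per-pixel temperature grid as a pseudo-color
image using a rainbow palette: low temperatures map to blue-dominant
colors, high temperatures to red-dominant ones.  This module provides the
forward rendering (temperature -> 8-bit RGB) and a nearest-point inverse
(RGB -> temperature) so that conventional ROI temperature measures can be
recovered from a rendered thermogram when the float temperature raster is
not available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

#: Default camera measurement range, degrees Celsius.
CAMERA_RANGE = (10.0, 50.0)

# blue - cyan - green - yellow - orange - red - white
_RAINBOW7 = (
    (0.0, (0, 0, 255)),
    (1 / 6, (0, 255, 255)),
    (2 / 6, (0, 255, 0)),
    (3 / 6, (255, 255, 0)),
    (4 / 6, (255, 165, 0)),
    (5 / 6, (255, 0, 0)),
    (1.0, (255, 255, 255)),
)

# Variant with a magenta band at medium-high temperatures.
_RAINBOW8_MAGENTA = (
    (0.0, (0, 0, 255)),
    (1 / 7, (0, 255, 255)),
    (2 / 7, (0, 255, 0)),
    (3 / 7, (255, 255, 0)),
    (4 / 7, (255, 165, 0)),
    (5 / 7, (255, 0, 255)),
    (6 / 7, (255, 0, 0)),
    (1.0, (255, 255, 255)),
)


@dataclass(frozen=True)
class RainbowPalette:
    """Piecewise-linear palette over temperature fraction in [0, 1].

    ``points`` is an ordered tuple of ``(fraction, (r, g, b))`` control
    points; colors between control points are linearly interpolated per
    channel and rounded to 8 bits.
    """

    points: tuple = field(default=_RAINBOW7)
    name: str = "rainbow7"

    def __post_init__(self) -> None:
        fracs = [p[0] for p in self.points]
        if fracs != sorted(fracs) or fracs[0] != 0.0 or fracs[-1] != 1.0:
            raise ValueError("palette control points must span [0, 1] in order")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def colors(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)

    def color_at(self, frac: np.ndarray) -> np.ndarray:
        """Interpolated 8-bit RGB color(s) at palette fraction(s)."""
        frac = np.clip(np.asarray(frac, dtype=float), 0.0, 1.0)
        out = np.empty(frac.shape + (3,), dtype=np.uint8)
        for c in range(3):
            out[..., c] = np.rint(
                np.interp(frac, self.fractions, self.colors[:, c])
            ).astype(np.uint8)
        return out


DEFAULT_PALETTE = RainbowPalette()
MAGENTA_PALETTE = RainbowPalette(points=_RAINBOW8_MAGENTA, name="rainbow8_magenta")

PALETTES = {p.name: p for p in (DEFAULT_PALETTE, MAGENTA_PALETTE)}


def temperature_to_rgb(
    field: np.ndarray,
    palette: RainbowPalette = DEFAULT_PALETTE,
    trange: tuple[float, float] = CAMERA_RANGE,
) -> np.ndarray:
    """Render a temperature field (degC) as an 8-bit RGB thermogram.

    Temperatures are clipped to ``trange`` and mapped linearly onto the
    palette fraction axis before per-channel interpolation.
    """
    tmin, tmax = trange
    if not tmin < tmax:
        raise ValueError(f"degenerate temperature range ({tmin}, {tmax})")
    frac = (np.asarray(field, dtype=float) - tmin) / (tmax - tmin)
    return palette.color_at(frac)


@lru_cache(maxsize=8)
def _inverse_lookup(palette: RainbowPalette, trange: tuple, samples: int):
    tmin, tmax = trange
    temps = np.linspace(tmin, tmax, samples)
    colors = temperature_to_rgb(temps, palette, trange).astype(float)
    # Collapse runs of identical quantized colors to their central
    # temperature; force exact endpoint colors back onto tmin / tmax.
    change = np.ones(samples, dtype=bool)
    change[1:] = np.any(colors[1:] != colors[:-1], axis=1)
    run_id = np.cumsum(change) - 1
    n_runs = run_id[-1] + 1
    rep_temp = np.zeros(n_runs)
    np.add.at(rep_temp, run_id, temps)
    counts = np.bincount(run_id)
    rep_temp /= counts
    rep_color = colors[change]
    lo, hi = palette.color_at(0.0), palette.color_at(1.0)
    rep_temp[np.all(rep_color == lo, axis=1)] = tmin
    rep_temp[np.all(rep_color == hi, axis=1)] = tmax
    return cKDTree(rep_color), rep_temp


def rgb_to_temperature(
    image: np.ndarray,
    palette: RainbowPalette = DEFAULT_PALETTE,
    trange: tuple[float, float] = CAMERA_RANGE,
    samples: int = 8192,
) -> np.ndarray:
    """Invert a palette rendering by nearest-point lookup on the curve.

    Colors that do not lie on the palette curve (annotations, gray pixels)
    snap to the nearest curve point rather than failing.
    """
    tmin, tmax = trange
    if not tmin < tmax:
        raise ValueError(f"degenerate temperature range ({tmin}, {tmax})")
    tree, rep_temp = _inverse_lookup(palette, tuple(trange), samples)
    img = np.asarray(image, dtype=float)
    flat = img.reshape(-1, 3)
    _, idx = tree.query(flat)
    return rep_temp[idx].reshape(img.shape[:-1])


def inversion_tolerance(
    palette: RainbowPalette = DEFAULT_PALETTE,
    trange: tuple[float, float] = CAMERA_RANGE,
    samples: int = 8192,
) -> float:
    """Half the widest constant-color temperature run: the worst-case
    round-trip error of ``rgb_to_temperature`` after 8-bit quantization."""
    tmin, tmax = trange
    temps = np.linspace(tmin, tmax, samples)
    colors = temperature_to_rgb(temps, palette, trange).astype(float)
    change = np.ones(samples, dtype=bool)
    change[1:] = np.any(colors[1:] != colors[:-1], axis=1)
    run_len = np.diff(np.append(np.flatnonzero(change), samples))
    step = temps[1] - temps[0]
    # sampled run widths underestimate the true widths by up to two lattice
    # steps; add one more step for the position of the run center
    return 0.5 * (run_len.max() + 2) * step + step
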