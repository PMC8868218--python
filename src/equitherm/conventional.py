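"""Conventional thermography measures: Tmax and Taver per ROI.

Tmax is the highest temperature recorded in an ROI, Taver the arithmetic
mean over the full ROI area — the two measures thermography software
reports for a segmented region.  Temperatures come from the float field
when present, otherwise from palette inversion of the rendered image.
"""

from __future__ import annotations

import numpy as np

from .palette import CAMERA_RANGE, DEFAULT_PALETTE, rgb_to_temperature

CONVENTIONAL_FEATURES = ("Tmax", "Taver")


def roi_temperatures(field: np.ndarray, rois) -> dict:
    """``{roi_label: {"Tmax": .., "Taver": ..}}`` over the mask pixels."""
    field = np.asarray(field, dtype=float)
    out = {}
    for label, mask in rois.items():
        if field.shape != mask.shape:
            raise ValueError(
                f"field dimensions {field.shape} do not match ROI {label} "
                f"mask dimensions {mask.shape}"
            )
        vals = field[mask]
        if vals.size == 0:
            raise ValueError(f"ROI {label} mask is empty")
        out[label] = {"Tmax": float(vals.max()), "Taver": float(vals.mean())}
    return out


def record_temperatures(record, rois, palette=DEFAULT_PALETTE,
                        trange=CAMERA_RANGE) -> dict:
    """ROI temperatures for one thermogram record, inverting the palette
    rendering when the float field is absent."""
    field = record.field
    if field is None:
        field = rgb_to_temperature(record.image, palette, trange)
    return roi_temperatures(field, rois)


def conventional_rows(record, rois, **kwargs) -> list:
    """Feature-table rows (channel ``IRT``) for one record."""
    temps = record_temperatures(record, rois, **kwargs)
    return [
        {
            "horse": record.horse,
            "re": record.re,
            "bs": record.bs,
            "roi": label,
            "channel": "IRT",
            "normalization": "none",
            "feature": name,
            "value": temps[label][name],
        }
        for label in sorted(temps)
        for name in CONVENTIONAL_FEATURES
    ]
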