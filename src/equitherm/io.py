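"""Disk formats for study bundles and feature tables.

Layout of a study directory::

    study/
      biomarkers.csv          horse,re,bs,WBC,...,AST
      rois.png                single-channel label raster, labels 1-4
      images/hHH_reR_bsB.png  8-bit RGB thermograms
      temps/hHH_reR_bsB.tif   32-bit float temperature rasters (optional)

Feature tables are long-format CSV with columns
``horse,re,bs,roi,channel,normalization,feature,value``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .rois import ROISet
from .synthetic import (
    BIOMARKER_NAMES,
    EffectModel,
    Study,
    StudyDesign,
    ThermogramRecord,
)

FEATURE_TABLE_COLUMNS = (
    "horse", "re", "bs", "roi", "channel", "normalization", "feature", "value",
)


def _record_stem(horse: int, re: int, bs: int) -> str:
    return f"h{horse:02d}_re{re}_bs{bs}"


def _write_png(path: Path, array: np.ndarray) -> None:
    # Serialize through a buffer so the byte stream is a pure function of
    # the pixel data (no timestamps or ancillary chunks).
    buf = _io.BytesIO()
    Image.fromarray(array).save(buf, format="PNG")
    path.write_bytes(buf.getvalue())


def write_study(study: Study, path: str | Path) -> Path:
    """Write a study bundle to ``path``; returns the directory path."""
    root = Path(path)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "temps").mkdir(exist_ok=True)
    _write_png(root / "rois.png", study.rois.labels_raster())
    for r in study.records:
        stem = _record_stem(r.horse, r.re, r.bs)
        _write_png(root / "images" / f"{stem}.png", r.image)
        tifffile.imwrite(
            root / "temps" / f"{stem}.tif", r.field.astype(np.float32)
        )
    study.biomarker_table().to_csv(root / "biomarkers.csv", index=False)
    return root


def read_study(path: str | Path) -> Study:
    """Read a study bundle written by :func:`write_study` (or assembled by
    hand to the same layout).  Temperature rasters are optional; images are
    read as plain 8-bit RGB with no palette assumptions."""
    root = Path(path)
    bio_path = root / "biomarkers.csv"
    if not bio_path.exists():
        raise FileNotFoundError(f"missing biomarker table: {bio_path}")
    table = pd.read_csv(bio_path)
    missing = [c for c in ("horse", "re", "bs") if c not in table.columns]
    if missing:
        raise ValueError(f"{bio_path}: missing column(s) {missing}")

    roi_path = root / "rois.png"
    if not roi_path.exists():
        raise FileNotFoundError(f"missing ROI raster: {roi_path}")
    rois = ROISet.from_labels(np.asarray(Image.open(roi_path)), source=str(roi_path))

    records = []
    for _, row in table.iterrows():
        horse, re, bs = int(row["horse"]), int(row["re"]), int(row["bs"])
        stem = _record_stem(horse, re, bs)
        img_path = root / "images" / f"{stem}.png"
        if not img_path.exists():
            raise FileNotFoundError(f"missing thermogram: {img_path}")
        image = np.asarray(Image.open(img_path).convert("RGB"))
        if image.shape[:2] != rois.shape:
            raise ValueError(
                f"{img_path}: image dimensions {image.shape[:2]} do not match "
                f"ROI raster dimensions {rois.shape}"
            )
        tif_path = root / "temps" / f"{stem}.tif"
        field = (
            tifffile.imread(tif_path).astype(float) if tif_path.exists() else None
        )
        if field is not None and field.shape != rois.shape:
            raise ValueError(
                f"{tif_path}: raster dimensions {field.shape} do not match "
                f"ROI raster dimensions {rois.shape}"
            )
        panel = {name: float(row[name]) for name in BIOMARKER_NAMES if name in row}
        records.append(ThermogramRecord(horse, re, bs, field, image, panel))

    horses = int(table["horse"].max())
    res = int(table["re"].max())
    h, w = rois.shape
    design = StudyDesign(
        n_horses=max(horses, 1), n_re=max(res, 2),
        image_height=h, image_width=w,
    )
    return Study(design, EffectModel(), rois, records)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing column(s) {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    table.loc[:, FEATURE_TABLE_COLUMNS].to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing feature table: {path}")
    return pd.read_csv(path)
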