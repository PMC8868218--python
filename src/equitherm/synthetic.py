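"""Synthetic equine thermography studies with known effect structure.

Emulates the repeated standardized-exercise design: ``n_horses`` horses,
``n_re`` daily exercise repetitions (RE), and two sampling times per RE
(BS 0 at rest before, BS 1 immediately after exercise), each sampling
producing one thermogram of the thoracolumbar region plus a 12-parameter
blood panel.  The generator encodes the structure the downstream analysis
is designed to recover:

* post-exercise surface warming concentrated over muscle ROIs (BS 1
  warmer and spatially more heterogeneous than BS 0 of the same RE);
* a per-(horse, RE) latent *cumulative exercise load* ``L = re + noise``
  shared by the coupled blood biomarkers (WBC, CPK, AST by default) and
  by the thermal heterogeneity driver, so that their across-RE trends at
  BS 1 are parallel up to independent noise;
* within-RE BS0 -> BS1 jumps without an across-RE trend for the acute
  markers (RBC, HGB, HCT, LAC).

All draws flow from a single seed through per-record child generators, so
a study bundle is a bit-identical function of its design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, field_validator
from scipy.ndimage import gaussian_filter

from .palette import CAMERA_RANGE, DEFAULT_PALETTE, RainbowPalette, temperature_to_rgb
from .rois import MUSCLE_ROIS, ROISet, default_roi_set

BIOMARKER_NAMES = (
    "WBC", "RBC", "HGB", "HCT", "MCV", "MCH",
    "MCHC", "LAC", "TSP", "CPK", "ALT", "AST",
)

#: Per-biomarker generative model: resting mean (BS 0), post-exercise
#: intercept (BS 1 value at RE = 0 on the latent-load axis), per-RE slope
#: at BS 1 for coupled biomarkers, marginal SD, and detection floor.
#: Means/SDs/slopes are set to the magnitudes printed for this study
#: population (e.g. CPK rising 202 -> 294 U/L between the first and sixth
#: post-exercise samples, SD ~ 70 U/L).
_BM = {
    #        bs0_mean bs1_base slope   sd    floor
    "WBC":  (8.2,     7.56,    0.44,   1.5,  0.01),   # x10^9/L
    "RBC":  (8.0,     9.5,     0.0,    0.6,  0.01),   # x10^12/L
    "HGB":  (8.3,     9.6,     0.0,    0.6,  0.01),   # mmol/L
    "HCT":  (36.0,    42.0,    0.0,    3.0,  0.01),   # %
    "MCV":  (45.0,    45.0,    0.0,    2.0,  0.01),   # fL
    "MCH":  (16.0,    16.0,    0.0,    1.0,  0.01),   # gL
    "MCHC": (21.0,    21.0,    0.0,    1.2,  0.01),   # mmol/L
    "LAC":  (0.9,     5.5,     0.0,    1.0,  1.0),    # mmol/L, assay floor
    "TSP":  (65.0,    68.0,    0.0,    4.0,  0.01),   # g/L
    "CPK":  (150.0,   183.6,   18.4,   70.0, 0.01),   # U/L
    "ALT":  (9.0,     10.0,    0.0,    3.0,  0.01),   # U/L
    "AST":  (250.0,   223.8,   14.2,   50.0, 0.01),   # U/L
}

# Variance partition (fractions of the marginal SD, scaled by noise_sd):
# shared latent load spread (RE units), between-horse offset, residual.
_LOAD_SD = 3.2          # latent load SD in RE units at noise_sd = 1
_HORSE_FRAC = 0.25      # between-horse offset fraction of biomarker SD
_RESID_COUPLED = 0.25   # residual fraction when the load term carries the rest
_RESID_PLAIN = 0.55     # residual fraction for draws without a load term
_HORSE_TEMP_SD = 0.3    # degC, between-horse baseline temperature offset
_SMOOTH_TEMP_SD = 0.2   # degC, smooth per-image field variation
_PIXEL_TEMP_SD = 0.05   # degC, per-pixel sensor noise


class StudyDesign(BaseModel):
    """Dimensions of a repeated-exercise thermography study."""

    model_config = {"extra": "forbid", "frozen": True}

    n_horses: int = Field(default=12, ge=1)
    n_re: int = Field(default=6, ge=2)
    n_bs: int = Field(default=2)
    image_height: int = Field(default=120, ge=16)
    image_width: int = Field(default=160, ge=16)
    seed: int = 0

    @field_validator("n_bs")
    @classmethod
    def _two_sampling_times(cls, v: int) -> int:
        if v != 2:
            raise ValueError("n_bs must be 2 (BS 0 before / BS 1 after exercise)")
        return v

    @property
    def n_images(self) -> int:
        return self.n_horses * self.n_re * self.n_bs


class EffectModel(BaseModel):
    """Magnitudes of the simulated exercise effect.

    ``re_warming`` is the post-exercise surface warming (degC) added over
    muscle ROIs at BS 1.  ``cumulative_slope`` scales, as a dimensionless
    multiplier, both the canonical per-RE biomarker slopes and the per-RE
    growth of thermal heterogeneity; 0 switches the across-RE trend off.
    ``noise_sd`` scales every stochastic term (0 = fully deterministic).
    """

    model_config = {"extra": "forbid", "frozen": True}

    baseline_temp: float = 26.0
    re_warming: float = Field(default=2.0, ge=0.0)
    cumulative_slope: float = 1.0
    noise_sd: float = Field(default=1.0, ge=0.0)
    coupled_biomarkers: tuple[str, ...] = ("WBC", "CPK", "AST")

    @field_validator("coupled_biomarkers")
    @classmethod
    def _known_names(cls, v):
        unknown = set(v) - set(BIOMARKER_NAMES)
        if unknown:
            raise ValueError(f"unknown biomarker(s): {sorted(unknown)}")
        return tuple(v)


NULL_EFFECT = EffectModel(re_warming=0.0, cumulative_slope=0.0, noise_sd=0.0)


@dataclass(frozen=True)
class ThermogramRecord:
    """One imaging + blood-sampling event."""

    horse: int
    re: int
    bs: int
    field: np.ndarray      # (H, W) float degC
    image: np.ndarray      # (H, W, 3) uint8
    panel: dict            # biomarker name -> value


@dataclass
class Study:
    """Full in-memory study bundle."""

    design: StudyDesign
    effect: EffectModel
    rois: ROISet
    records: list = field(default_factory=list)
    palette: RainbowPalette = DEFAULT_PALETTE

    def __len__(self) -> int:
        return len(self.records)

    def biomarker_table(self):
        import pandas as pd

        rows = [
            {"horse": r.horse, "re": r.re, "bs": r.bs, **r.panel}
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=["horse", "re", "bs", *BIOMARKER_NAMES])

    def record(self, horse: int, re: int, bs: int) -> ThermogramRecord:
        for r in self.records:
            if (r.horse, r.re, r.bs) == (horse, re, bs):
                return r
        raise KeyError((horse, re, bs))


def _validate_indices(design: StudyDesign, horse: int, re: int, bs: int) -> None:
    if not 1 <= horse <= design.n_horses:
        raise ValueError(f"horse index {horse} outside 1..{design.n_horses}")
    if not 1 <= re <= design.n_re:
        raise ValueError(f"RE index {re} outside 1..{design.n_re}")
    if bs not in (0, 1):
        raise ValueError(f"BS index {bs} must be 0 or 1")


def generate_temperature_field(
    design: StudyDesign,
    effect: EffectModel,
    horse: int,
    re: int,
    bs: int,
    rng: np.random.Generator,
    rois: ROISet | None = None,
    horse_temp_offset: float = 0.0,
    load: float | None = None,
) -> np.ndarray:
    """Per-pixel surface temperature grid (degC) for one imaging event.

    A smooth baseline field carries the between-horse offset and slowly
    varying noise; at BS 1 each muscle ROI receives one broad warm blob of
    amplitude ``re_warming`` plus small warm sub-blobs whose count grows
    with the latent exercise load, so the ROI's spatial variance rises
    linearly across REs.  Values are clamped to the camera range.
    """
    _validate_indices(design, horse, re, bs)
    h, w = design.image_height, design.image_width
    if rois is None:
        rois = default_roi_set(h, w)
    if load is None:
        load = float(re)
    nsd = effect.noise_sd

    field_ = np.full((h, w), effect.baseline_temp + horse_temp_offset, dtype=float)
    if nsd > 0:
        smooth = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 8.0)
        sd = smooth.std()
        if sd > 0:
            field_ += _SMOOTH_TEMP_SD * nsd * smooth / sd
        field_ += _PIXEL_TEMP_SD * nsd * rng.standard_normal((h, w))

    if bs == 1:
        yy, xx = np.mgrid[0:h, 0:w]
        amp_sub = 0.2 * effect.re_warming + 0.8 * effect.cumulative_slope
        n_sub = max(0, int(round(3 + 4 * effect.cumulative_slope * load)))
        for label in MUSCLE_ROIS:
            r0, r1, c0, c1 = rois.bbox(label)
            rh, rw = r1 - r0, c1 - c0
            # broad exercise-warming blob, jittered around the ROI center
            cy = (r0 + r1) / 2 + rng.uniform(-0.06, 0.06) * rh
            cx = (c0 + c1) / 2 + rng.uniform(-0.06, 0.06) * rw
            sy, sx = max(1.0, 0.50 * rh), max(1.0, 0.50 * rw)
            field_ += effect.re_warming * np.exp(
                -((yy - cy) ** 2 / (2 * sy**2) + (xx - cx) ** 2 / (2 * sx**2))
            )
            # heterogeneity sub-blobs: count tracks the latent load
            s_sub = max(1.0, 0.06 * min(rh, rw))
            for _ in range(n_sub):
                by = rng.uniform(r0 + s_sub, r1 - s_sub)
                bx = rng.uniform(c0 + s_sub, c1 - s_sub)
                field_ += amp_sub * np.exp(
                    -((yy - by) ** 2 + (xx - bx) ** 2) / (2 * s_sub**2)
                )

    return np.clip(field_, CAMERA_RANGE[0], CAMERA_RANGE[1])


def generate_biomarker_panel(
    effect: EffectModel,
    horse: int,
    re: int,
    bs: int,
    rng: np.random.Generator,
    horse_offsets: dict | None = None,
    load: float | None = None,
) -> dict:
    """One 12-parameter blood panel.

    Coupled biomarkers at BS 1 follow ``intercept + slope * load`` with the
    shared latent load; acute markers jump between BS 0 and BS 1 without an
    across-RE trend.  LAC draws below the 1.0 mmol/L detection limit are
    stored as 1.0; all values are positive.
    """
    if bs not in (0, 1):
        raise ValueError(f"BS index {bs} must be 0 or 1")
    if re < 1:
        raise ValueError(f"RE index {re} must be >= 1")
    if load is None:
        load = float(re)
    nsd = effect.noise_sd
    panel = {}
    for name in BIOMARKER_NAMES:
        bs0_mean, bs1_base, slope, sd, floor = _BM[name]
        offset = (horse_offsets or {}).get(name, 0.0)
        coupled = bs == 1 and name in effect.coupled_biomarkers and slope != 0.0
        if coupled:
            mean = bs1_base + slope * effect.cumulative_slope * load
            resid = _RESID_COUPLED
        else:
            mean = bs1_base if bs == 1 else bs0_mean
            resid = _RESID_PLAIN
        value = mean + offset + resid * sd * nsd * rng.standard_normal()
        panel[name] = max(value, floor)
    return panel


def generate_study(design: StudyDesign, effect: EffectModel) -> Study:
    """Generate a full study bundle: thermograms, masks and blood panels.

    Returns ``n_horses * n_re * 2`` records; the whole bundle is a
    deterministic function of ``design.seed``.
    """
    h, w = design.image_height, design.image_width
    rois = default_roi_set(h, w)
    ss = np.random.SeedSequence(design.seed)
    ss_common, ss_records = ss.spawn(2)
    rng0 = np.random.default_rng(ss_common)

    nsd = effect.noise_sd
    horse_temp = _HORSE_TEMP_SD * nsd * rng0.standard_normal(design.n_horses + 1)
    horse_bio = {
        hh: {
            name: _HORSE_FRAC * _BM[name][3] * nsd * rng0.standard_normal()
            for name in BIOMARKER_NAMES
        }
        for hh in range(1, design.n_horses + 1)
    }
    load_eps = rng0.standard_normal((design.n_horses + 1, design.n_re + 1))

    n_records = design.n_images
    child_seeds = ss_records.spawn(n_records)
    records = []
    i = 0
    for horse in range(1, design.n_horses + 1):
        for re in range(1, design.n_re + 1):
            load = re + _LOAD_SD * nsd * load_eps[horse, re]
            for bs in (0, 1):
                rng = np.random.default_rng(child_seeds[i])
                i += 1
                fld = generate_temperature_field(
                    design, effect, horse, re, bs, rng,
                    rois=rois, horse_temp_offset=horse_temp[horse], load=load,
                )
                image = temperature_to_rgb(fld, DEFAULT_PALETTE, CAMERA_RANGE)
                panel = generate_biomarker_panel(
                    effect, horse, re, bs, rng,
                    horse_offsets=horse_bio[horse], load=load,
                )
                records.append(ThermogramRecord(horse, re, bs, fld, image, panel))
    return Study(design, effect, rois, records)
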