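"""The 88 texture features over one gray channel restricted to one ROI.

Eight feature families are computed, following the QMazda-style naming:

* HS   — 14 first-order histogram statistics;
* GM   — 6 statistics of the gradient-magnitude map;
* AM   — 5 causal autoregressive model parameters (Teta1..4, sigma);
* GT   — 24 Gabor-transform magnitudes (6 wavelengths x 4 orientations);
* HOG  — 8 magnitude-weighted orientation-histogram bins;
* GRLM — 7 gray-level run-length statistics averaged over 4 directions;
* GLCM — 12 Haralick statistics of the symmetric co-occurrence matrix,
  averaged over 4 directions x 9 distances;
* GLCH — the same 12 statistics from the asymmetric matrix.

Gray levels are 1-based integers in [1, 2^n].  Matrix families (GRLM,
GLCM, GLCH) operate on channels requantized to a coarser bit depth
(default 6) so co-occurrence matrices stay dense on small ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

HS_NAMES = (
    "HistArea", "HistMean", "HistVariance", "HistSkewness", "HistKurtosis",
    "HistPerc01", "HistPerc10", "HistPerc50", "HistPerc90", "HistPerc99",
    "HistDomn01", "HistDomn10", "HistMaxm01", "HistMaxm10",
)
GM_NAMES = (
    "GradArea", "GradMean", "GradVariance", "GradSkewness", "GradKurtosis",
    "GradNonZeros",
)
AM_NAMES = ("Teta1", "Teta2", "Teta3", "Teta4", "sigma")
GABOR_WAVELENGTHS = (4, 6, 8, 12, 16, 24)
GABOR_ORIENTATIONS = {"H": 0.0, "V": 90.0, "N": 45.0, "Z": 135.0}
GT_NAMES = tuple(
    f"Gab{lam}{o}{lam // 2}Mag"
    for lam in GABOR_WAVELENGTHS
    for o in ("H", "V", "N", "Z")
)
HOG_NAMES = tuple(f"HogO8b{i}" for i in range(8))
GRLM_NAMES = (
    "RLNonUni", "GLevNonUn", "LngREmph", "ShrtREmp", "Fraction",
    "MRLNonUni", "MGLevNonUn",
)
GLCM_NAMES = (
    "Area", "AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDefMom",
    "SumAverg", "SumEntrp", "SumVarnc", "Entropy", "DifVarnc", "DifEntrp",
)

FAMILY_NAMES = {
    "HS": HS_NAMES,
    "GM": GM_NAMES,
    "AM": AM_NAMES,
    "GT": GT_NAMES,
    "HOG": HOG_NAMES,
    "GRLM": GRLM_NAMES,
    "GLCM": GLCM_NAMES,
    "GLCH": GLCM_NAMES,
}
ALL_FAMILIES = tuple(FAMILY_NAMES)
N_FEATURES = sum(len(v) for v in FAMILY_NAMES.values())  # 88

#: Direction name -> (dy, dx) unit offset; 45 deg runs up-right.
DIRECTIONS = {"0": (0, 1), "45": (-1, 1), "90": (1, 0), "135": (1, 1)}


@dataclass(frozen=True)
class GLCMConfig:
    """Offsets and conventions for the co-occurrence families."""

    distances: tuple = tuple(range(1, 10))
    directions: tuple = ("0", "45", "90", "135")
    log_base: str = "e"  # "e" or "2"
    bit_depth: int = 6   # gray levels for GRLM/GLCM/GLCH

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.distances):
            raise ValueError("GLCM distances must be >= 1")
        unknown = set(self.directions) - set(DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown direction(s) {sorted(unknown)}")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")

    @property
    def log(self):
        return np.log if self.log_base == "e" else np.log2


def _moments(vals: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, population variance, skewness and excess kurtosis; the shape
    moments of a degenerate (zero-variance) sample are defined as 0."""
    mean = float(vals.mean())
    var = float(((vals - mean) ** 2).mean())
    if var <= 0:
        return mean, 0.0, 0.0, 0.0
    sd = np.sqrt(var)
    skew = float((((vals - mean) / sd) ** 3).mean())
    kurt = float((((vals - mean) / sd) ** 4).mean()) - 3.0
    return mean, var, skew, kurt


# ---------------------------------------------------------------- HS ----

def hist_features(
    data: np.ndarray,
    mask: np.ndarray,
    bit_depth: int = 8,
    dom_widths: tuple[int, int] = (1, 10),
    maxm_normalized: bool = True,
) -> dict:
    """First-order histogram statistics of the ROI gray levels.

    Percentiles are the smallest gray level whose CDF reaches the target
    quantile.  ``HistDomn`` is the histogram mode position at bin widths 1
    and 10 (bin lower-edge gray level); ``HistMaxm`` the corresponding
    maximal bin count divided by the ROI area.
    """
    vals = np.asarray(data)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    n = vals.size
    levels = 2**bit_depth
    counts = np.bincount(vals, minlength=levels + 1)[1:]
    mean, var, skew, kurt = _moments(vals.astype(float))
    cdf = np.cumsum(counts) / n
    out = {
        "HistArea": float(n),
        "HistMean": mean,
        "HistVariance": var,
        "HistSkewness": skew,
        "HistKurtosis": kurt,
    }
    for q, name in zip(
        (0.01, 0.10, 0.50, 0.90, 0.99),
        ("HistPerc01", "HistPerc10", "HistPerc50", "HistPerc90", "HistPerc99"),
    ):
        out[name] = float(np.argmax(cdf >= q) + 1)
    for width, tag in zip(dom_widths, ("01", "10")):
        if width == 1:
            binned = counts
        else:
            pad = (-len(counts)) % width
            binned = np.pad(counts, (0, pad)).reshape(-1, width).sum(axis=1)
            edges0 = None
        k = int(np.argmax(binned))
        out[f"HistDomn{tag}"] = float(k + 1 if width == 1 else 1 + width * k)
        mx = float(binned.max())
        out[f"HistMaxm{tag}"] = mx / n if maxm_normalized else mx
    return out


# ---------------------------------------------------------------- GM ----

def _interior(mask: np.ndarray) -> np.ndarray:
    """ROI pixels whose 4-neighborhood lies inside both ROI and frame."""
    mask = np.asarray(mask, dtype=bool)
    interior = binary_erosion(mask)  # cross-shaped structuring element
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    return interior


def _gradients(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(data, dtype=float)
    gy, gx = np.gradient(f)  # central differences in the interior
    return gx, gy


def gradient_features(data: np.ndarray, mask: np.ndarray) -> dict:
    """Statistics of the gradient-magnitude map over the ROI interior.

    The magnitude is sqrt(Gx^2 + Gy^2) with central differences; only
    pixels whose four neighbors lie inside the ROI (1-pixel erosion)
    contribute.
    """
    interior = _interior(mask)
    if not interior.any():
        raise ValueError("ROI too thin: no interior after 1-pixel erosion")
    gx, gy = _gradients(data)
    mag = np.hypot(gx, gy)[interior]
    mean, var, skew, kurt = _moments(mag)
    return {
        "GradArea": float(mag.size),
        "GradMean": mean,
        "GradVariance": var,
        "GradSkewness": skew,
        "GradKurtosis": kurt,
        "GradNonZeros": float((mag > 1e-12).mean()),
    }


# ---------------------------------------------------------------- AM ----

def ar_features(data: np.ndarray, mask: np.ndarray) -> dict:
    """Causal autoregressive model fit over the ROI.

    Each eligible pixel is predicted from its left, top-left, top and
    top-right neighbors; theta is the least-squares solution (minimum-norm
    when the design is rank-deficient) and sigma the RMS residual.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h, w = data.shape
    if h < 2 or w < 3:
        raise ValueError("ROI raster too small for causal neighborhoods")
    center = mask[1:, 1:-1]
    left = mask[1:, :-2]
    topl = mask[:-1, :-2]
    top = mask[:-1, 1:-1]
    topr = mask[:-1, 2:]
    elig = center & left & topl & top & topr
    if not elig.any():
        raise ValueError("no ROI pixels with all four causal neighbors in ROI")
    y = data[1:, 1:-1][elig]
    X = np.column_stack(
        [
            data[1:, :-2][elig],
            data[:-1, :-2][elig],
            data[:-1, 1:-1][elig],
            data[:-1, 2:][elig],
        ]
    )
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    sigma = float(np.sqrt(np.mean(resid**2)))
    return {
        "Teta1": float(theta[0]),
        "Teta2": float(theta[1]),
        "Teta3": float(theta[2]),
        "Teta4": float(theta[3]),
        "sigma": sigma,
    }


# ---------------------------------------------------------------- GT ----

def gabor_kernel(wavelength: float, theta_deg: float) -> np.ndarray:
    """Complex Gabor kernel, sigma = wavelength / 2, truncated at 3 sigma,
    DC-corrected to zero mean."""
    sigma = wavelength / 2.0
    r = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1].astype(float)
    theta = np.deg2rad(theta_deg)
    arg = 2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / wavelength
    kernel = np.exp(-(xx**2 + yy**2) / (2 * sigma**2)) * np.exp(1j * arg)
    return kernel - kernel.mean()


def gabor_support_radius(wavelength: float) -> int:
    return int(np.ceil(3 * (wavelength / 2.0)))


def gabor_features(data: np.ndarray, mask: np.ndarray) -> dict:
    """Mean Gabor response magnitude over supported ROI pixels.

    The response at a pixel is the correlation of the image with the
    zero-DC complex kernel; only pixels whose kernel support lies fully
    inside the frame contribute.  Wavelengths whose support fits nowhere
    yield NaN; if even the smallest wavelength is unsupported the ROI is
    too small and an error is raised.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    h, w = data.shape
    out = {}
    any_supported = False
    for lam in GABOR_WAVELENGTHS:
        r = gabor_support_radius(lam)
        supported = np.zeros_like(mask)
        if h > 2 * r and w > 2 * r:
            supported[r: h - r, r: w - r] = True
        valid = mask & supported
        for letter, theta in GABOR_ORIENTATIONS.items():
            name = f"Gab{lam}{letter}{lam // 2}Mag"
            if not valid.any():
                out[name] = np.nan
                continue
            any_supported = True
            kernel = gabor_kernel(lam, theta)
            # correlation == convolution with the flipped conjugate kernel
            resp = fftconvolve(data, np.conj(kernel[::-1, ::-1]), mode="same")
            out[name] = float(np.abs(resp)[valid].mean())
    if not any_supported:
        raise ValueError(
            "ROI smaller than the smallest Gabor kernel support "
            f"(radius {gabor_support_radius(GABOR_WAVELENGTHS[0])})"
        )
    return out


# --------------------------------------------------------------- HOG ----

def hog_features(data: np.ndarray, mask: np.ndarray, n_bins: int = 8) -> dict:
    """Magnitude-weighted unsigned gradient-orientation histogram.

    Orientations in [0, 180) are split into ``n_bins`` equal bins and the
    histogram is normalized to sum 1; a zero-gradient ROI yields the
    all-zero vector.
    """
    interior = _interior(mask)
    if not interior.any():
        raise ValueError("ROI too thin: no interior after 1-pixel erosion")
    gx, gy = _gradients(data)
    mag = np.hypot(gx, gy)[interior]
    ang = np.degrees(np.arctan2(gy, gx))[interior] % 180.0
    bins = np.minimum((ang / (180.0 / n_bins)).astype(int), n_bins - 1)
    nonzero = mag > 1e-12
    hist = np.bincount(bins[nonzero], weights=mag[nonzero], minlength=n_bins)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return {f"HogO8b{i}": float(v) for i, v in enumerate(hist)}


# -------------------------------------------------------------- GRLM ----

def _strips(data: np.ndarray, mask: np.ndarray, direction: str):
    """Maximal 1-D strips of (values, validity) along a direction."""
    a = np.asarray(data)
    m = np.asarray(mask, dtype=bool)
    if direction == "0":
        return [(a[i], m[i]) for i in range(a.shape[0])]
    if direction == "90":
        return [(a[:, j], m[:, j]) for j in range(a.shape[1])]
    if direction == "135":
        src_a, src_m = a, m
    else:  # "45": up-right runs are the diagonals of the flipped raster
        src_a, src_m = a[::-1], m[::-1]
    h, w = src_a.shape
    return [
        (src_a.diagonal(k), src_m.diagonal(k)) for k in range(-h + 1, w)
    ]


def glrlm_matrix(data: np.ndarray, mask: np.ndarray, direction: str) -> np.ndarray:
    """Run matrix p(gray, length) of maximal equal-gray runs inside the
    ROI along one direction; runs break at ROI boundaries."""
    levels = int(np.asarray(data)[np.asarray(mask, dtype=bool)].max())
    max_len = max(np.asarray(data).shape)
    P = np.zeros((levels + 1, max_len + 1), dtype=np.int64)
    for vals, valid in _strips(data, mask, direction):
        if len(vals) == 0 or not valid.any():
            continue
        v = np.where(valid, vals, -1)
        change = np.empty(len(v), dtype=bool)
        change[0] = True
        change[1:] = v[1:] != v[:-1]
        starts = np.flatnonzero(change)
        lengths = np.diff(np.append(starts, len(v)))
        keep = v[starts] >= 0
        np.add.at(P, (v[starts][keep], lengths[keep]), 1)
    return P


def _glrlm_direction_features(P: np.ndarray, n_pixels: int) -> dict:
    n_r = P.sum()
    if n_r == 0:
        raise ValueError("no runs in ROI")
    lengths = np.arange(P.shape[1], dtype=float)
    lengths[0] = 1.0  # unused (no zero-length runs); avoids 0-division
    by_len = P.sum(axis=0).astype(float)
    by_gray = P.sum(axis=1).astype(float)
    short = float((by_len / lengths**2).sum() / n_r)
    long_ = float((by_len * np.arange(P.shape[1]) ** 2).sum() / n_r)
    glnu = float((by_gray**2).sum() / n_r)
    rlnu = float((by_len**2).sum() / n_r)
    return {
        "RLNonUni": rlnu,
        "GLevNonUn": glnu,
        "LngREmph": long_,
        "ShrtREmp": short,
        "Fraction": float(n_r / n_pixels),
        "MRLNonUni": float(rlnu / n_r),
        "MGLevNonUn": float(glnu / n_r),
    }


def glrlm_features(
    data: np.ndarray,
    mask: np.ndarray,
    directions: tuple = ("0", "45", "90", "135"),
) -> dict:
    """Run-length statistics averaged over the four directions."""
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise ValueError("empty ROI")
    per_dir = [
        _glrlm_direction_features(glrlm_matrix(data, mask, d), n_pixels)
        for d in directions
    ]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GRLM_NAMES
    }


# -------------------------------------------------------------- GLCM ----

def glcm_matrix(
    data: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int],
    n_levels: int,
    symmetric: bool,
) -> np.ndarray:
    """Co-occurrence count matrix over ordered in-ROI pixel pairs at one
    (dy, dx) offset; the symmetric variant is C + C^T."""
    a = np.asarray(data)
    m = np.asarray(mask, dtype=bool)
    dy, dx = offset
    h, w = a.shape
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    yd = slice(max(0, dy), min(h, h + dy))
    xd = slice(max(0, dx), min(w, w + dx))
    valid = m[ys, xs] & m[yd, xd]
    i = a[ys, xs][valid].astype(np.int64)
    j = a[yd, xd][valid].astype(np.int64)
    C = np.bincount(
        (i - 1) * n_levels + (j - 1), minlength=n_levels * n_levels
    ).reshape(n_levels, n_levels)
    return C + C.T if symmetric else C


def haralick_stats(C: np.ndarray, log) -> dict:
    """Twelve Haralick statistics of one co-occurrence count matrix."""
    total = C.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    P = C / total
    L = P.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_x = float(i @ pi)
    mu_y = float(i @ pj)
    var_x = float(((i - mu_x) ** 2) @ pi)
    var_y = float(((i - mu_y) ** 2) @ pj)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    nz = P > 0

    # diagonal and anti-diagonal marginals
    ksum = np.arange(2, 2 * L + 1, dtype=float)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, P.ravel())
    kdiff = np.arange(0, L, dtype=float)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())

    sum_avg = float(ksum @ p_sum)
    sum_var = float(((ksum - sum_avg) ** 2) @ p_sum)
    snz = p_sum > 0
    dnz = p_diff > 0
    diff_mean = float(kdiff @ p_diff)
    if var_x > 0 and var_y > 0:
        correlat = float((float((ii * jj * P).sum()) - mu_x * mu_y)
                         / np.sqrt(var_x * var_y))
    else:
        correlat = 0.0
    return {
        "Area": float(total),
        "AngScMom": float((P**2).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlat": correlat,
        "SumOfSqs": float(((ii - mu_x) ** 2 * P).sum()),
        "InvDefMom": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "SumAverg": sum_avg,
        "SumEntrp": float(-(p_sum[snz] * log(p_sum[snz])).sum()),
        "SumVarnc": sum_var,
        "Entropy": float(-(P[nz] * log(P[nz])).sum()),
        "DifVarnc": float(((kdiff - diff_mean) ** 2) @ p_diff),
        "DifEntrp": float(-(p_diff[dnz] * log(p_diff[dnz])).sum()),
    }


def glcm_features(
    data: np.ndarray,
    mask: np.ndarray,
    config: GLCMConfig = GLCMConfig(),
    symmetric: bool = True,
    per_offset: bool = False,
):
    """Haralick statistics averaged over all (direction, distance) offsets.

    ``symmetric=True`` gives the GLCM variant, ``False`` the asymmetric
    GLCH variant.  Offsets with no valid in-ROI pair are skipped; if no
    offset has a valid pair an error is raised.  With ``per_offset`` the
    un-aggregated per-offset dictionaries are returned alongside.
    """
    n_levels = 2**config.bit_depth
    per = {}
    for d in config.distances:
        for name in config.directions:
            dy, dx = DIRECTIONS[name]
            C = glcm_matrix(data, mask, (dy * d, dx * d), n_levels, symmetric)
            if C.sum() == 0:
                continue
            per[(name, d)] = haralick_stats(C, config.log)
    if not per:
        raise ValueError("no valid pixel pairs at any offset")
    agg = {
        k: float(np.mean([stats[k] for stats in per.values()]))
        for k in GLCM_NAMES
    }
    return (agg, per) if per_offset else agg


# -------------------------------------------------------- extraction ----

@dataclass(frozen=True)
class TextureConfig:
    """Which families to compute and at which matrix bit depth."""

    families: tuple = ALL_FAMILIES
    glcm: GLCMConfig = dc_field(default_factory=GLCMConfig)

    def __post_init__(self) -> None:
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown texture families {sorted(unknown)}")


def extract_channel(
    channel,
    mask: np.ndarray,
    config: TextureConfig = TextureConfig(),
) -> dict:
    """All configured features of one channel variant on one ROI.

    Returns ``{"FAMILY.Name": value}``; a family that cannot be computed
    (thin ROI, degenerate channel) contributes NaNs for all its features,
    never a partial vector.
    """
    from .color import requantize

    data = channel.data
    coarse = requantize(data, channel.bit_depth, config.glcm.bit_depth)
    runners = {
        "HS": lambda: hist_features(data, mask, channel.bit_depth),
        "GM": lambda: gradient_features(data, mask),
        "AM": lambda: ar_features(data, mask),
        "GT": lambda: gabor_features(data, mask),
        "HOG": lambda: hog_features(data, mask),
        "GRLM": lambda: glrlm_features(coarse, mask),
        "GLCM": lambda: glcm_features(coarse, mask, config.glcm, symmetric=True),
        "GLCH": lambda: glcm_features(coarse, mask, config.glcm, symmetric=False),
    }
    out = {}
    for family in ALL_FAMILIES:
        if family not in config.families:
            continue
        names = FAMILY_NAMES[family]
        try:
            values = runners[family]()
        except ValueError as exc:
            logger.warning("%s features unavailable (%s); recording NaN",
                           family, exc)
            values = {name: np.nan for name in names}
        out.update({f"{family}.{name}": values[name] for name in names})
    return out


def extract_all(
    image: np.ndarray,
    rois,
    config: TextureConfig = TextureConfig(),
    normalized_variant: str = "minmax",
    bit_depth: int = 8,
    meta: dict | None = None,
):
    """Feature table rows for one image: every channel variant x ROI.

    With the full family set this is 88 features x 24 channel variants x
    4 ROIs = 8448 rows (2112 combinations per ROI).  Returns a pandas
    DataFrame in the long feature-table format.
    """
    import pandas as pd

    from .color import channel_variants

    meta = meta or {}
    rows = []
    for roi_label, mask in rois.items():
        for channel in channel_variants(
            image, mask, normalized_variant=normalized_variant,
            bit_depth=bit_depth,
        ):
            features = extract_channel(channel, mask, config)
            for name, value in features.items():
                rows.append(
                    {
                        **meta,
                        "roi": roi_label,
                        "channel": channel.label,
                        "normalization": channel.normalization,
                        "feature": name,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
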