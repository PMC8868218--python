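"""Independent brute-force reference implementations of the 88 features.

Naive pair/run enumeration, direct window sums and direct moment loops,
written for clarity rather than speed; they share no code path with the
package's vectorized implementations and serve as oracles in the tests
and the acceptance checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import pinv


def hist_oracle(data, mask, bit_depth=8):
    vals = sorted(int(data[y, x]) for y, x in zip(*np.nonzero(mask)))
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    if var > 0:
        sd = math.sqrt(var)
        skew = sum(((v - mean) / sd) ** 3 for v in vals) / n
        kurt = sum(((v - mean) / sd) ** 4 for v in vals) / n - 3
    else:
        skew = kurt = 0.0
    out = {
        "HistArea": float(n), "HistMean": mean, "HistVariance": var,
        "HistSkewness": skew, "HistKurtosis": kurt,
    }
    levels = 2**bit_depth
    counts = {g: 0 for g in range(1, levels + 1)}
    for v in vals:
        counts[v] += 1
    for q, name in ((0.01, "HistPerc01"), (0.10, "HistPerc10"),
                    (0.50, "HistPerc50"), (0.90, "HistPerc90"),
                    (0.99, "HistPerc99")):
        cum = 0
        for g in range(1, levels + 1):
            cum += counts[g]
            if cum / n >= q:
                out[name] = float(g)
                break
    for width, tag in ((1, "01"), (10, "10")):
        best_k, best_count = 0, -1
        n_bins = (levels + width - 1) // width
        for k in range(n_bins):
            c = sum(counts.get(g, 0)
                    for g in range(1 + width * k, 1 + width * (k + 1)))
            if c > best_count:
                best_k, best_count = k, c
        out[f"HistDomn{tag}"] = float(1 + width * best_k)
        out[f"HistMaxm{tag}"] = best_count / n
    return out


def _interior_pixels(mask):
    h, w = mask.shape
    return [
        (y, x)
        for y in range(1, h - 1)
        for x in range(1, w - 1)
        if mask[y, x] and mask[y - 1, x] and mask[y + 1, x]
        and mask[y, x - 1] and mask[y, x + 1]
    ]


def _grad_at(data, y, x):
    gx = (float(data[y, x + 1]) - float(data[y, x - 1])) / 2.0
    gy = (float(data[y + 1, x]) - float(data[y - 1, x])) / 2.0
    return gx, gy


def gradient_oracle(data, mask):
    pix = _interior_pixels(mask)
    mags = []
    for y, x in pix:
        gx, gy = _grad_at(data, y, x)
        mags.append(math.sqrt(gx * gx + gy * gy))
    n = len(mags)
    mean = sum(mags) / n
    var = sum((m - mean) ** 2 for m in mags) / n
    if var > 0:
        sd = math.sqrt(var)
        skew = sum(((m - mean) / sd) ** 3 for m in mags) / n
        kurt = sum(((m - mean) / sd) ** 4 for m in mags) / n - 3
    else:
        skew = kurt = 0.0
    return {
        "GradArea": float(n), "GradMean": mean, "GradVariance": var,
        "GradSkewness": skew, "GradKurtosis": kurt,
        "GradNonZeros": sum(m > 1e-12 for m in mags) / n,
    }


def ar_oracle(data, mask):
    h, w = mask.shape
    rows_X, rows_y = [], []
    for y in range(1, h):
        for x in range(1, w - 1):
            if (mask[y, x] and mask[y, x - 1] and mask[y - 1, x - 1]
                    and mask[y - 1, x] and mask[y - 1, x + 1]):
                rows_X.append([
                    float(data[y, x - 1]), float(data[y - 1, x - 1]),
                    float(data[y - 1, x]), float(data[y - 1, x + 1]),
                ])
                rows_y.append(float(data[y, x]))
    X = np.array(rows_X)
    yv = np.array(rows_y)
    theta = pinv(X) @ yv  # minimum-norm least squares
    resid = yv - X @ theta
    return {
        "Teta1": theta[0], "Teta2": theta[1], "Teta3": theta[2],
        "Teta4": theta[3], "sigma": math.sqrt(float((resid**2).mean())),
    }


def hog_oracle(data, mask, n_bins=8):
    pix = _interior_pixels(mask)
    hist = [0.0] * n_bins
    for y, x in pix:
        gx, gy = _grad_at(data, y, x)
        mag = math.sqrt(gx * gx + gy * gy)
        if mag <= 1e-12:
            continue
        ang = math.degrees(math.atan2(gy, gx)) % 180.0
        hist[min(int(ang / (180.0 / n_bins)), n_bins - 1)] += mag
    total = sum(hist)
    if total > 0:
        hist = [v / total for v in hist]
    return {f"HogO8b{i}": hist[i] for i in range(n_bins)}


def gabor_oracle(data, mask, wavelengths=(4, 6, 8, 12, 16, 24)):
    """Direct window-sum correlation with the zero-DC complex kernel."""
    h, w = data.shape
    data = np.asarray(data, dtype=float)
    out = {}
    for lam in wavelengths:
        sigma = lam / 2.0
        r = int(np.ceil(3 * sigma))
        yy, xx = np.mgrid[-r: r + 1, -r: r + 1].astype(float)
        gauss = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
        for letter, theta_deg in (("H", 0.0), ("V", 90.0), ("N", 45.0),
                                  ("Z", 135.0)):
            theta = math.radians(theta_deg)
            carrier = np.exp(
                1j * 2 * np.pi * (xx * math.cos(theta) + yy * math.sin(theta))
                / lam
            )
            kernel = gauss * carrier
            kernel = kernel - kernel.mean()
            mags = []
            for y in range(r, h - r):
                for x in range(r, w - r):
                    if not mask[y, x]:
                        continue
                    window = data[y - r: y + r + 1, x - r: x + r + 1]
                    mags.append(abs(np.sum(window * kernel)))
            name = f"Gab{lam}{letter}{lam // 2}Mag"
            out[name] = float(np.mean(mags)) if mags else float("nan")
    return out


_DIR_STEPS = {"0": (0, 1), "45": (-1, 1), "90": (1, 0), "135": (1, 1)}


def glrlm_oracle(data, mask, directions=("0", "45", "90", "135")):
    h, w = mask.shape
    n_p = int(mask.sum())
    per_dir = []
    for dname in directions:
        dy, dx = _DIR_STEPS[dname]
        runs = []  # (gray, length)
        visited = set()
        for y in range(h):
            for x in range(w):
                if not mask[y, x] or (y, x) in visited:
                    continue
                # only start a run at a pixel with no in-ROI predecessor
                py, px = y - dy, x - dx
                if (0 <= py < h and 0 <= px < w and mask[py, px]
                        and data[py, px] == data[y, x]):
                    continue
                g = data[y, x]
                length = 0
                cy, cx = y, x
                while (0 <= cy < h and 0 <= cx < w and mask[cy, cx]
                       and data[cy, cx] == g):
                    visited.add((cy, cx))
                    length += 1
                    cy, cx = cy + dy, cx + dx
                runs.append((int(g), length))
        n_r = len(runs)
        short = sum(1.0 / (ln * ln) for _, ln in runs) / n_r
        long_ = sum(float(ln * ln) for _, ln in runs) / n_r
        grays = {}
        lens = {}
        for g, ln in runs:
            grays[g] = grays.get(g, 0) + 1
            lens[ln] = lens.get(ln, 0) + 1
        glnu = sum(c * c for c in grays.values()) / n_r
        rlnu = sum(c * c for c in lens.values()) / n_r
        per_dir.append({
            "RLNonUni": rlnu, "GLevNonUn": glnu, "LngREmph": long_,
            "ShrtREmp": short, "Fraction": n_r / n_p,
            "MRLNonUni": rlnu / n_r, "MGLevNonUn": glnu / n_r,
        })
        # every ROI pixel must belong to exactly one maximal run
        assert sum(ln for _, ln in runs) == n_p
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def glcm_matrix_oracle(data, mask, offset, n_levels, symmetric):
    h, w = mask.shape
    dy, dx = offset
    C = np.zeros((n_levels, n_levels), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if not (0 <= y2 < h and 0 <= x2 < w):
                continue
            if mask[y, x] and mask[y2, x2]:
                C[data[y, x] - 1, data[y2, x2] - 1] += 1
                if symmetric:
                    C[data[y2, x2] - 1, data[y, x] - 1] += 1
    return C


def haralick_oracle(C, log_base="e"):
    log = math.log if log_base == "e" else math.log2
    total = float(C.sum())
    L = C.shape[0]
    P = {(i + 1, j + 1): C[i, j] / total
         for i in range(L) for j in range(L) if C[i, j] > 0}
    mu_x = sum(i * p for (i, _), p in P.items())
    mu_y = sum(j * p for (_, j), p in P.items())
    var_x = sum((i - mu_x) ** 2 * p for (i, _), p in P.items())
    var_y = sum((j - mu_y) ** 2 * p for (_, j), p in P.items())
    p_sum, p_diff = {}, {}
    for (i, j), p in P.items():
        p_sum[i + j] = p_sum.get(i + j, 0.0) + p
        p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p
    sum_avg = sum(k * p for k, p in p_sum.items())
    diff_avg = sum(k * p for k, p in p_diff.items())
    if var_x > 0 and var_y > 0:
        correlat = (sum(i * j * p for (i, j), p in P.items()) - mu_x * mu_y) \
            / math.sqrt(var_x * var_y)
    else:
        correlat = 0.0
    return {
        "Area": total,
        "AngScMom": sum(p * p for p in P.values()),
        "Contrast": sum((i - j) ** 2 * p for (i, j), p in P.items()),
        "Correlat": correlat,
        "SumOfSqs": sum((i - mu_x) ** 2 * p for (i, _), p in P.items()),
        "InvDefMom": sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items()),
        "SumAverg": sum_avg,
        "SumEntrp": -sum(p * log(p) for p in p_sum.values()),
        "SumVarnc": sum((k - sum_avg) ** 2 * p for k, p in p_sum.items()),
        "Entropy": -sum(p * log(p) for p in P.values()),
        "DifVarnc": sum((k - diff_avg) ** 2 * p for k, p in p_diff.items()),
        "DifEntrp": -sum(p * log(p) for p in p_diff.values()),
    }


def glcm_oracle(data, mask, n_levels, symmetric, distances=range(1, 10),
                directions=("0", "45", "90", "135"), log_base="e"):
    stats = []
    for d in distances:
        for dname in directions:
            dy, dx = _DIR_STEPS[dname]
            C = glcm_matrix_oracle(data, mask, (dy * d, dx * d), n_levels,
                                   symmetric)
            if C.sum() == 0:
                continue
            stats.append(haralick_oracle(C, log_base))
    return {k: float(np.mean([s[k] for s in stats])) for k in stats[0]}
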