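"""The statistical pipeline: distribution routing, paired and
repeated-measures comparisons, and slope-parallelism feature selection.

Routing follows the classical scheme: Shapiro-Wilk decides between the
Gaussian route (paired t-test; repeated-measures ANOVA with
Geisser-Greenhouse correction and Tukey post hoc) and the non-Gaussian
route (Wilcoxon matched pairs; Friedman with Dunn post hoc).

Feature selection is an ANCOVA-style slope-parallelism test: a texture
feature "relates to" a blood biomarker when their across-RE regression
lines at BS 1 have statistically indistinguishable slopes and the pooled
slope is significantly non-zero.  Slope equality is the extra-sum-of-
squares F-test between the common-slope and separate-slopes fits; when
slopes pool, intercept equality is tested the same way against the
single-line fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_TARGETS = ("WBC", "CPK", "AST")


# ------------------------------------------------------------ routing ----

def route_test(sample, alpha: float = 0.05) -> str:
    """``'gaussian'`` iff the Shapiro-Wilk p-value is >= alpha.

    A degenerate (constant) sample cannot be Gaussian-routed and returns
    ``'non_gaussian'``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality routing needs at least 3 observations")
    if np.ptp(x) == 0:
        return "non_gaussian"
    _, p = sps.shapiro(x)
    return "gaussian" if p >= alpha else "non_gaussian"


def compare_bs(before, after, route: str) -> float:
    """Two-sided paired comparison of BS 0 vs BS 1 samples."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    diffs = after - before
    if route == "gaussian":
        if np.all(diffs == 0):
            return 1.0
        return float(sps.ttest_rel(after, before).pvalue)
    if np.all(diffs == 0):
        raise ValueError("all paired differences are zero on the Wilcoxon route")
    # matched-pairs convention: drop zero differences, mid-rank ties
    return float(sps.wilcoxon(after, before, zero_method="wilcox").pvalue)


# ------------------------------------------------- repeated measures ----

def gg_epsilon(matrix: np.ndarray) -> float:
    """Geisser-Greenhouse sphericity correction from the double-centered
    covariance of the subjects x conditions matrix; in [1/(k-1), 1]."""
    x = np.asarray(matrix, dtype=float)
    k = x.shape[1]
    S = np.cov(x, rowvar=False)
    Sd = (
        S
        - S.mean(axis=0, keepdims=True)
        - S.mean(axis=1, keepdims=True)
        + S.mean()
    )
    denom = (k - 1) * (Sd**2).sum()
    if denom <= 0:
        return 1.0
    eps = np.trace(Sd) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _rm_anova(x: np.ndarray) -> tuple[float, float, float, float, int]:
    """Repeated-measures one-way ANOVA with GG-corrected p.

    Returns (F, p, epsilon, ms_error, df_error).
    """
    n, k = x.shape
    grand = x.mean()
    treat = x.mean(axis=0)
    subj = x.mean(axis=1)
    ss_treat = n * ((treat - grand) ** 2).sum()
    ss_subj = k * ((subj - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_treat - ss_subj
    df_t, df_e = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df_e
    if ms_err <= 1e-300:
        if ss_treat <= 1e-300:
            return 0.0, 1.0, 1.0, 0.0, df_e
        return np.inf, 0.0, 1.0, 0.0, df_e
    F = (ss_treat / df_t) / ms_err
    eps = gg_epsilon(x)
    p = float(sps.f.sf(F, eps * df_t, eps * df_e))
    return float(F), p, eps, float(ms_err), df_e


def compare_re(matrix, route: str) -> dict:
    """Across-RE comparison of a subjects x RE matrix.

    Gaussian route: repeated-measures ANOVA with Geisser-Greenhouse
    correction, Tukey post hoc on the studentized range.  Non-Gaussian
    route: Friedman test with Dunn's Bonferroni-adjusted post hoc.
    Returns ``{'omnibus_p', 'epsilon', 'pairwise': {(i, j): p}}`` with
    1-based column pairs.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 3:
        raise ValueError("need a complete subjects x conditions matrix (k >= 3)")
    if np.isnan(x).any():
        raise ValueError("missing cells in repeated-measures matrix")
    n, k = x.shape
    pairs = list(itertools.combinations(range(k), 2))
    scale = max(float(np.abs(x).max()), 1.0)
    if np.ptp(x - x.mean(axis=1, keepdims=True)) <= 1e-10 * scale:
        # identical conditions for every subject
        return {
            "omnibus_p": 1.0, "epsilon": 1.0, "statistic": 0.0,
            "pairwise": {(i + 1, j + 1): 1.0 for i, j in pairs},
        }
    if route == "gaussian":
        F, p, eps, ms_err, df_e = _rm_anova(x)
        treat = x.mean(axis=0)
        pairwise = {}
        for i, j in pairs:
            if ms_err <= 0:
                pairwise[(i + 1, j + 1)] = 0.0 if treat[i] != treat[j] else 1.0
                continue
            q = abs(treat[i] - treat[j]) / np.sqrt(ms_err / n)
            pairwise[(i + 1, j + 1)] = float(sps.studentized_range.sf(q, k, df_e))
        return {"omnibus_p": p, "epsilon": eps, "statistic": F,
                "pairwise": pairwise}
    stat, p = sps.friedmanchisquare(*[x[:, j] for j in range(k)])
    ranks = sps.rankdata(x, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    m = len(pairs)
    pairwise = {}
    for i, j in pairs:
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        pairwise[(i + 1, j + 1)] = float(min(1.0, 2 * sps.norm.sf(z) * m))
    return {"omnibus_p": float(p), "epsilon": None, "statistic": float(stat),
            "pairwise": pairwise}


# ------------------------------------------------- slope parallelism ----

@dataclass
class SeriesPair:
    """Two (x, y) point clouds sharing the RE axis: a biomarker series and
    a feature series, one point per horse per RE."""

    x_a: np.ndarray
    y_a: np.ndarray
    x_b: np.ndarray
    y_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        self.x_a = np.asarray(self.x_a, dtype=float)
        self.y_a = np.asarray(self.y_a, dtype=float)
        self.x_b = np.asarray(self.x_b, dtype=float)
        self.y_b = np.asarray(self.y_b, dtype=float)
        for x, y, lbl in ((self.x_a, self.y_a, self.label_a),
                          (self.x_b, self.y_b, self.label_b)):
            if x.shape != y.shape or x.size < 3:
                raise ValueError(f"group {lbl}: need >= 3 (x, y) points")
            if np.ptp(x) == 0:
                raise ValueError(f"group {lbl}: degenerate x (all equal)")


@dataclass
class ParallelismResult:
    slope_a: float
    slope_b: float
    p_slope_equal: float
    pooled_slope: float | None
    p_intercept_equal: float | None
    pooled_intercept: float | None
    p_slope_nonzero: float
    related: bool


def _ols(x: np.ndarray, y: np.ndarray):
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    sse = ((y - intercept - slope * x) ** 2).sum()
    return slope, intercept, sse, sxx, sxy


def _f_test(sse_reduced, sse_full, df_diff, df_full, scale):
    """Extra-sum-of-squares F-test with a guard for exact fits."""
    delta = max(sse_reduced - sse_full, 0.0)
    tiny = 1e-12 * max(scale, 1e-300)
    if sse_full <= tiny:
        if delta <= tiny:
            return 0.0, 1.0
        return np.inf, 0.0
    F = (delta / df_diff) / (sse_full / df_full)
    return float(F), float(sps.f.sf(F, df_diff, df_full))


def fit_parallelism(
    pair: SeriesPair,
    alpha: float = 0.05,
    alpha_nonzero: float = 0.05,
) -> ParallelismResult:
    """Slope-parallelism ANCOVA for one (biomarker, feature) pair.

    Fits separate simple regressions per group, tests slope equality by
    the extra-sum-of-squares F-test; when slopes do not differ (p > alpha)
    the pooled slope is fitted and intercept equality tested the same way,
    pooling the intercept when it too does not differ.  The pair is
    ``related`` when the slopes are parallel and the pooled slope is
    significantly non-zero.
    """
    sa, ia, sse_a, sxx_a, sxy_a = _ols(pair.x_a, pair.y_a)
    sb, ib, sse_b, sxx_b, sxy_b = _ols(pair.x_b, pair.y_b)
    n = pair.x_a.size + pair.x_b.size
    scale = ((pair.y_a - pair.y_a.mean()) ** 2).sum() + (
        (pair.y_b - pair.y_b.mean()) ** 2
    ).sum()

    # common slope, separate intercepts
    slope_c = (sxy_a + sxy_b) / (sxx_a + sxx_b)
    int_a = pair.y_a.mean() - slope_c * pair.x_a.mean()
    int_b = pair.y_b.mean() - slope_c * pair.x_b.mean()
    sse_common = (
        ((pair.y_a - int_a - slope_c * pair.x_a) ** 2).sum()
        + ((pair.y_b - int_b - slope_c * pair.x_b) ** 2).sum()
    )
    _, p_slope_equal = _f_test(sse_common, sse_a + sse_b, 1, n - 4, scale)

    pooled_slope = pooled_intercept = p_intercept_equal = None
    if p_slope_equal > alpha:
        pooled_slope = float(slope_c)
        x_all = np.concatenate([pair.x_a, pair.x_b])
        y_all = np.concatenate([pair.y_a, pair.y_b])
        slope_s, int_s, sse_single, _, _ = _ols(x_all, y_all)
        _, p_intercept_equal = _f_test(sse_single, sse_common, 1, n - 3, scale)
        if p_intercept_equal > alpha:
            pooled_intercept = float(int_s)
        # pooled-slope t-test against 0
        sigma2 = sse_common / (n - 3)
        if sigma2 <= 1e-12 * max(scale, 1e-300):
            p_nz = 1.0 if abs(slope_c) <= 1e-12 else 0.0
        else:
            t = slope_c / np.sqrt(sigma2 / (sxx_a + sxx_b))
            p_nz = float(2 * sps.t.sf(abs(t), n - 3))
    else:
        # slopes differ: report the weaker of the per-group non-zero tests
        ps = []
        for slope, sse, sxx, m in ((sa, sse_a, sxx_a, pair.x_a.size),
                                   (sb, sse_b, sxx_b, pair.x_b.size)):
            sigma2 = sse / (m - 2) if m > 2 else 0.0
            if sigma2 <= 1e-12 * max(scale, 1e-300):
                ps.append(1.0 if abs(slope) <= 1e-12 else 0.0)
            else:
                t = slope / np.sqrt(sigma2 / sxx)
                ps.append(float(2 * sps.t.sf(abs(t), m - 2)))
        p_nz = max(ps)

    related = bool(p_slope_equal > alpha and p_nz < alpha_nonzero)
    return ParallelismResult(
        slope_a=float(sa),
        slope_b=float(sb),
        p_slope_equal=float(p_slope_equal),
        pooled_slope=pooled_slope,
        p_intercept_equal=p_intercept_equal,
        pooled_intercept=pooled_intercept,
        p_slope_nonzero=float(p_nz),
        related=related,
    )


def rescale_to(feature_values, biomarker_values) -> np.ndarray:
    """Affinely map a feature series onto the biomarker's sample mean and
    SD so their slopes are commensurate; a constant feature series maps to
    the constant biomarker mean."""
    f = np.asarray(feature_values, dtype=float)
    b = np.asarray(biomarker_values, dtype=float)
    sd_f = f.std(ddof=1)
    if sd_f == 0:
        return np.full_like(f, b.mean())
    return (f - f.mean()) / sd_f * b.std(ddof=1) + b.mean()


# ---------------------------------------------------------- selection ----

def select_related(
    features: pd.DataFrame,
    biomarkers: pd.DataFrame,
    targets=DEFAULT_TARGETS,
    alpha: float = 0.05,
    alpha_nonzero: float = 0.05,
    scale_align: str = "match_moments",
    bs: int = 1,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Slope-parallelism selection over every (ROI, biomarker, feature).

    ``features`` is a long feature table; series are formed at the given
    sampling time (default BS 1) with x = RE index, pooling horses as
    replicates.  With ``scale_align='match_moments'`` each feature series
    is affinely rescaled onto the biomarker's scale before slope
    comparison; ``'raw'`` compares raw slopes.  Returns one row per pair
    with the parallelism statistics and the ``related`` flag.
    """
    if scale_align not in ("match_moments", "raw"):
        raise ValueError("scale_align must be 'match_moments' or 'raw'")
    feat = features[(features["bs"] == bs) & features["value"].notna()]
    bio = biomarkers[biomarkers["bs"] == bs]
    rows = []
    for target in targets:
        if target not in bio.columns:
            raise ValueError(f"biomarker table has no column {target!r}")
        merged_bio = bio[["horse", "re", target]].dropna()
        x_bio = merged_bio["re"].to_numpy(dtype=float)
        y_bio = merged_bio[target].to_numpy(dtype=float)
        for (roi, channel, norm, feature), grp in feat.groupby(
            ["roi", "channel", "normalization", "feature"], sort=True
        ):
            x_f = grp["re"].to_numpy(dtype=float)
            y_f = grp["value"].to_numpy(dtype=float)
            if x_f.size < 3 or np.ptp(x_f) == 0:
                continue
            y_cmp = rescale_to(y_f, y_bio) if scale_align == "match_moments" else y_f
            res = fit_parallelism(
                SeriesPair(x_bio, y_bio, x_f, y_cmp, target, feature),
                alpha=alpha, alpha_nonzero=alpha_nonzero,
            )
            rows.append(
                {
                    "roi": roi,
                    "biomarker": target,
                    "channel": channel,
                    "normalization": norm,
                    "feature": feature,
                    "slope_biomarker": res.slope_a,
                    "slope_feature": res.slope_b,
                    "p_slope_equal": res.p_slope_equal,
                    "pooled_slope": res.pooled_slope,
                    "p_intercept_equal": res.p_intercept_equal,
                    "p_slope_nonzero": res.p_slope_nonzero,
                    "related": res.related,
                }
            )
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        # Benjamini-Hochberg on the non-zero-slope p-values (off by default,
        # matching the per-pair p < alpha usage)
        p = out["p_slope_nonzero"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(p)
        q[order] = np.clip(adj, 0, 1)
        out["q_slope_nonzero"] = q
        out["related"] = out["related"] & (q < alpha_nonzero)
    return out


def format_selection_matrix(selection: pd.DataFrame) -> str:
    """Summary-matrix text: per ROI and feature family, which channel
    letters relate to which biomarkers."""
    if selection.empty or not selection["related"].any():
        return "no related (biomarker, feature) pairs\n"
    sel = selection[selection["related"]].copy()
    sel["family"] = sel["feature"].str.split(".").str[0]
    sel["letter"] = sel["channel"].str.split(".").str[-1]
    lines = []
    for roi in sorted(sel["roi"].unique()):
        lines.append(f"ROI {roi}")
        sub = sel[sel["roi"] == roi]
        for family in sorted(sub["family"].unique()):
            fam = sub[sub["family"] == family]
            cells = []
            for bm in sorted(fam["biomarker"].unique()):
                letters = sorted(set(fam.loc[fam["biomarker"] == bm, "letter"]))
                cells.append(f"{bm}: {','.join(letters)}")
            lines.append(f"  {family:5s} " + " | ".join(cells))
    return "\n".join(lines) + "\n"
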