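"""Monte-Carlo validation experiments for the analysis pipeline.

These drive the package end to end on synthetic studies with known
structure: type-I error of the slope-equality test under the null, the
ANCOVA pooled-slope identity, recovery of the engineered biomarker-
coupled texture feature, and calibration of the synthetic biomarker
panel against the magnitudes the study design targets.
"""

from __future__ import annotations

import numpy as np

from .color import NormalizationScheme, normalize
from .stats import SeriesPair, fit_parallelism, rescale_to
from .synthetic import EffectModel, StudyDesign, generate_study
from .texture import hist_features

#: Image size used for simulation experiments; small enough that a study
#: renders in well under a second, large enough that every ROI holds a
#: meaningful pixel population.
EXPERIMENT_SHAPE = (60, 80)
#: The "low noise" coupled scenario used for parameter recovery.
COUPLED_EFFECT = EffectModel(noise_sd=0.2)
NULL_TREND_EFFECT = EffectModel(cumulative_slope=0.0)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def slope_equality_type1(
    n_sim: int = 2000,
    seed: int = 0,
    n_points: int = 12,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the slope-equality F-test when both series come
    from the same linear model with iid Gaussian noise."""
    rng = np.random.default_rng(seed)
    x = np.tile(np.arange(1, 7, dtype=float), max(1, n_points // 6))[:n_points]
    rejections = 0
    for _ in range(n_sim):
        y_a = 1.0 + 2.0 * x + rng.standard_normal(x.size)
        y_b = 1.0 + 2.0 * x + rng.standard_normal(x.size)
        res = fit_parallelism(SeriesPair(x, y_a, x, y_b))
        rejections += res.p_slope_equal < alpha
    return rejections / n_sim


def pooled_slope_identity_error(n_sim: int = 200, seed: int = 0) -> float:
    """Maximum deviation between the pooled ANCOVA slope and the
    Sxx-weighted average of the group slopes (an algebraic identity)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_sim):
        x_a = rng.uniform(0, 10, 12)
        x_b = rng.uniform(0, 10, 15)
        y_a = rng.normal(2 * x_a + 1, 1.0)
        y_b = rng.normal(2 * x_b + 3, 1.0)
        pair = SeriesPair(x_a, y_a, x_b, y_b)
        res = fit_parallelism(pair, alpha=1e-12)  # force pooling
        sxx_a = ((x_a - x_a.mean()) ** 2).sum()
        sxx_b = ((x_b - x_b.mean()) ** 2).sum()
        expected = (res.slope_a * sxx_a + res.slope_b * sxx_b) / (sxx_a + sxx_b)
        if res.pooled_slope is not None:
            worst = max(worst, abs(res.pooled_slope - expected))
    return worst


def _red_variance_series(study, roi_label: int):
    """(re, value) arrays of the red-channel histogram variance over one
    ROI for every BS 1 thermogram, via the package's extraction path."""
    mask = study.rois[roi_label]
    scheme = NormalizationScheme("none", 8)
    xs, ys = [], []
    for rec in study.records:
        if rec.bs != 1:
            continue
        data, _ = normalize(rec.image[..., 0].astype(float), scheme, mask)
        feats = hist_features(data, mask)
        xs.append(float(rec.re))
        ys.append(feats["HistVariance"])
    return np.array(xs), np.array(ys)


def _biomarker_series(study, name: str):
    table = study.biomarker_table()
    sub = table[table["bs"] == 1]
    return sub["re"].to_numpy(dtype=float), sub[name].to_numpy(dtype=float)


def recovery_rates(
    n_studies: int = 100,
    seed: int = 0,
    effect: EffectModel = COUPLED_EFFECT,
    biomarker: str = "CPK",
    coupled_roi: int = 3,
    control_roi: int = 2,
    alpha: float = 0.05,
) -> dict:
    """Selection rates of the engineered coupled feature vs an uncoupled
    control over seeded coupled studies.

    The coupled feature is the red-channel histogram variance over a
    muscle ROI (its across-RE BS 1 trend shares the latent exercise load
    with the coupled biomarkers); the control is the same feature over the
    thoracic-spine ROI, which receives no exercise warming and therefore
    carries no trend.
    """
    h, w = EXPERIMENT_SHAPE
    coupled_hits = control_hits = 0
    for s in _spawn_seeds(seed, n_studies):
        design = StudyDesign(image_height=h, image_width=w, seed=s)
        study = generate_study(design, effect)
        x_bio, y_bio = _biomarker_series(study, biomarker)
        for roi, counter in ((coupled_roi, "coupled"), (control_roi, "control")):
            x_f, y_f = _red_variance_series(study, roi)
            y_cmp = rescale_to(y_f, y_bio)
            res = fit_parallelism(
                SeriesPair(x_bio, y_bio, x_f, y_cmp, biomarker, "R.HS.Variance"),
                alpha=alpha, alpha_nonzero=alpha,
            )
            if res.related:
                if counter == "coupled":
                    coupled_hits += 1
                else:
                    control_hits += 1
    return {
        "n_studies": n_studies,
        "coupled_rate": coupled_hits / n_studies,
        "control_rate": control_hits / n_studies,
    }


def null_selection_rate(
    n_studies: int = 50,
    seed: int = 0,
    effect: EffectModel = NULL_TREND_EFFECT,
    alpha: float = 0.05,
) -> float:
    """Fraction of (biomarker, feature) pairs flagged as related when the
    generator couples nothing (cumulative_slope = 0): the empirical
    false-positive rate of the selection procedure."""
    h, w = EXPERIMENT_SHAPE
    flags = []
    for s in _spawn_seeds(seed, n_studies):
        design = StudyDesign(image_height=h, image_width=w, seed=s)
        study = generate_study(design, effect)
        for biomarker in ("WBC", "CPK", "AST"):
            x_bio, y_bio = _biomarker_series(study, biomarker)
            for roi in (1, 2, 3, 4):
                x_f, y_f = _red_variance_series(study, roi)
                y_cmp = rescale_to(y_f, y_bio)
                res = fit_parallelism(
                    SeriesPair(x_bio, y_bio, x_f, y_cmp), alpha=alpha,
                )
                flags.append(res.related)
    return float(np.mean(flags))


def cpk_calibration(n_seeds: int = 20, seed: int = 0) -> dict:
    """Sample mean of the synthetic CPK panel at the sixth post-exercise
    sampling (RE 6, BS 1) across seeded default studies."""
    effect = EffectModel()
    values = []
    for s in _spawn_seeds(seed, n_seeds):
        design = StudyDesign(image_height=16, image_width=16, seed=s)
        study = generate_study(design, effect)
        table = study.biomarker_table()
        sub = table[(table["re"] == 6) & (table["bs"] == 1)]
        values.extend(sub["CPK"].tolist())
    values = np.asarray(values)
    return {
        "n": values.size,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
    }
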