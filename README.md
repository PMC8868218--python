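# equitherm

Texture analysis of equine thoracolumbar thermograms for non-invasive
monitoring of exercise effect.

## The problem

Blood biomarkers of exercise effect in horses — white blood cell count
(WBC), creatine phosphokinase (CPK) and aspartate aminotransferase (AST)
— accumulate across repeated daily exercise, but measuring them requires
venipuncture and laboratory work. Infrared thermography (IRT) is
contactless, yet the conventional measures (maximal and average ROI
temperature, Tmax / Taver) mostly reflect the acute post-exercise warm-up
and carry little information about cumulative load. The hypothesis this
pipeline operationalizes: the *texture* of the pseudo-color thermogram —
in particular variance-family statistics of the red channel over the
back-muscle regions — tracks the cumulative biomarkers where plain
temperatures do not.

`equitherm` implements the full analysis as a tested, reusable package:

1. **Synthetic study generation** (`equitherm.synthetic`) — a repeated
   standardized-exercise design (12 horses × 6 exercise repetitions (RE)
   × 2 sampling times: BS 0 before, BS 1 after exercise = 144
   thermograms), with post-exercise warming concentrated over muscle
   ROIs, a latent per-(horse, RE) exercise load shared by the coupled
   biomarkers and the thermal heterogeneity, and a 12-parameter blood
   panel calibrated to realistic equine magnitudes.
2. **Palette I/O** (`equitherm.palette`, `equitherm.io`) — rendering of
   temperature fields through a monotone rainbow palette (blue = cold,
   red = hot) over the camera range 10.0–50.0 °C, nearest-point palette
   inversion, and PNG/TIFF/CSV study bundles.
3. **Color models** (`equitherm.color`) — decomposition into the 12
   components of RGB, YUV, YIQ (BT.601) and HSB, each analyzed
   un-normalized (R, G, …) and after ROI-based gray-level normalization
   (r, g, …): `I_out = clamp(round(2ⁿ·(I_in − MIN)/(MAX − MIN)) + 1, 1, 2ⁿ)`
   with MIN/MAX from μ±3σ, min–max, or the 1st/99th percentiles.
4. **88 texture features** (`equitherm.texture`) — eight families per
   channel variant and ROI: histogram statistics (14), gradient map (6),
   causal autoregressive model (5), Gabor transform (24), histogram of
   oriented gradients (8), gray-level run-length matrix (7), and the 12
   Haralick statistics of the symmetric (GLCM) and asymmetric (GLCH)
   co-occurrence matrices averaged over 4 directions × distances 1–9.
   That is 88 × 24 channel variants = 2112 combinations per ROI.
5. **Statistics** (`equitherm.stats`) — Shapiro–Wilk routing, paired
   t / Wilcoxon BS comparisons, repeated-measures ANOVA with
   Geisser–Greenhouse correction / Friedman across REs, and the
   **slope-parallelism selection**: for each (biomarker, feature) pair the
   across-RE regressions at BS 1 are compared by the extra-sum-of-squares
   F-test; if the slopes do not differ (p > 0.05) a pooled slope is
   fitted and intercepts compared the same way. A feature *relates to* a
   biomarker when the slopes are parallel and the pooled slope is
   significantly non-zero.

## Worked example

```python
from equitherm import (EffectModel, StudyDesign, generate_study,
                       extract_all, select_related)

study = generate_study(
    StudyDesign(image_height=60, image_width=80, seed=1), EffectModel())
print(len(study))                        # 144 thermograms

rec = study.record(horse=1, re=1, bs=1)
table = extract_all(rec.image, study.rois,
                    meta={"horse": 1, "re": 1, "bs": 1})
print(table.groupby("roi").size())       # 2112 rows per ROI
```

Running the numbered analysis (`python analysis/01_simulate_study.py
--seed 1` … `05_validation_experiments.py`) prints, for seed 1:

```
wrote 144 thermograms (12 horses x 6 REs x 2 BSs) to results/study
post-exercise muscle-ROI warming: 1.90 +/- 0.45 degC (min 1.21)
CPK BS1 mean by RE: 203.2  204.2  234.6  238.4  284.0  288.5
...
WBC   BS jumps 3/6 REs, across-RE BS1 p = 0.0169 -> cumulative effect marker
RBC   BS jumps 6/6 REs, across-RE BS1 p = 0.8948 -> acute marker
CPK   BS jumps 6/6 REs, across-RE BS1 p = 0.0044 -> cumulative effect marker
AST   BS jumps 2/6 REs, across-RE BS1 p = 0.0029 -> cumulative effect marker
```

i.e. the screening recovers the cumulative markers (WBC, CPK, AST — a
rising post-exercise trend across repetitions) and the acute markers
(RBC, HGB, HCT, LAC — a jump after every exercise bout but no trend),
and the selection stage then flags red-channel variance-family features
over muscle ROIs as parallel to the cumulative biomarkers.

There is also a thin CLI over the same stages:

```sh
equitherm run --config cfg.yaml --seed 1 --out-dir results/run
```

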