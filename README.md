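# ramanmargin

Intraoperative assessment of breast-tumor surgical margins from portable
Raman spectra: a tested pipeline for preprocessing tissue spectra,
selecting discriminative wavenumber bands, classifying sites with PCA-LDA,
and tracking healthy-to-tumor transitions along margin transects.

## The problem

During breast-conserving surgery the surgeon must decide, by eye, where
tumor ends and healthy tissue begins; positive margins found a week later by
histopathology mean a second operation.  Portable near-infrared Raman
spectrometers (785 nm CCD systems and 1064 nm InGaAs systems) can read a
tissue site's biochemical fingerprint in seconds: malignant tissue shows
elevated nucleic-acid and protein bands (e.g. 941, 1002–1006, 1331 cm⁻¹)
and depressed lipid bands (1302–1303, 1439–1442, 1653–1657, 1746,
2850 cm⁻¹).  This package implements the full analysis such an instrument
needs behind it, exercised end to end on a synthetic spectrum generator
that emulates both instruments and the healthy/tumor band biochemistry —
so every stage is testable without patient data.

## The method

1. **Preprocessing** — cosmic-ray despiking (running-median + robust-z
   rule), iterative shifted-window spline estimation of the fluorescence
   background, subtraction, and area normalization to unit integral over
   400–1800 cm⁻¹ (1064 nm) or 400–3200 cm⁻¹ (785 nm).
2. **Band selection** — channelwise class means with 95% t-intervals
   (x̄ ± t₍ₙ₋₁₎·s/√n); wavenumber runs where the healthy and tumor
   envelopes separate become candidate bands, scored by integrated gap
   area.  Windows overlapping surgical-ink Raman lines (693, 1260, 1348,
   1398, 1541, 1597 cm⁻¹) are excluded.  Reference sets of 12 (1064 nm)
   and 17 (785 nm) bands ship with the package.
3. **Classification** — band features (windowed mean intensities) are
   mean-centered, compressed by PCA (covariance eigendecomposition; the
   first 3 components carry >98% of the variance), and classified by a
   Gaussian linear discriminant with pooled covariance and minimum
   expected misclassification cost.  Performance is estimated by
   leave-one-out cross-validation and reported as integer-percent
   sensitivity / specificity / accuracy with tumor as the positive class.
4. **Transit analysis** — ordered site sequences crossing a visible margin
   are classified per site; a boundary is called wherever consecutive
   thresholded posteriors disagree.

## Worked example

```python
from ramanmargin import (
    default_config, simulate_cohort, preprocess_cohort,
    reference_bands, extract_band_features, fit_pca, loo_cross_validate,
)

cfg = default_config(1064, seed=0)                  # 1064 nm instrument
cohort = preprocess_cohort(simulate_cohort(28, 29, 0, cfg))
features = extract_band_features(cohort, reference_bands(1064))
pca = fit_pca(features)
print(f"PC1-3 capture {pca.cum_percent[2]:.1f}% of variance")
report = loo_cross_validate(features, k=3)
print(f"confusion hh={report.hh} ht={report.ht} th={report.th} tt={report.tt}")
print(f"sens {report.sensitivity}% spec {report.specificity}% acc {report.accuracy}%")
```

prints

```
PC1-3 capture 98.7% of variance
confusion hh=28 ht=0 th=0 tt=29
sens 100% spec 100% acc 100%
```

i.e. on the default synthetic cohort (28 healthy / 29 tumor sites) the
12-band feature table concentrates 98.7% of its variance in three
principal components and the cross-validated classifier separates the two
tissue classes completely.  The `analysis/` scripts run the same chain as
a narrative study — cohorts for both instruments, band selection, ink
exclusion (16 of 17 bands survive), PCA tables, and a ten-site margin
transit — writing their tables to `results/`.

There is also a CLI:

```bash
raman-margin run --seed 0 --out-dir runs/demo     # full pipeline
raman-margin simulate --profile 785 --transit H,H,M,T,T --seed 1 --out-dir t1
```

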