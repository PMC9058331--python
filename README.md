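# irhisto

FTIR spectral histopathology in Python: digital de-paraffinization of
hyperspectral tissue images, K-means tissue segmentation, and PCA–LDA
pathology classification under leave-one-sample-out cross-validation, with a
synthetic hyperspectral tissue generator providing ground truth for testing.

## The problem

Distinguishing epithelial misplacement (pseudo-invasion) from invasive
adenocarcinoma in large colonic adenomatous polyps is one of the hardest
calls in diagnostic gastrointestinal histopathology. Mid-infrared
hyperspectral imaging offers a label-free alternative: an FPA-based FTIR
microscope records an absorbance spectrum at every ~1.1 µm pixel of an
unstained FFPE section, and the fingerprint region (1000–1800 cm⁻¹)
carries the biomolecular signatures — sugars (1040 cm⁻¹), DNA (1078,
1238 cm⁻¹), proteins (1160, amide II 1546, amide I 1654 cm⁻¹),
phospholipids (1726 cm⁻¹) — that differ between normal mucosa, adenoma,
epithelial misplacement and cancer. This package implements the full
analysis chain for such data, for spectroscopists and computational
pathologists who want a tested, reusable reference implementation.

## The method

1. **Digital de-paraffinization (EMSC).** Each observed spectrum *s* is
   decomposed by ordinary least squares as

   *s* ≈ *m*·*r* + Σᵢ *bᵢ*·*pᵢ* + Σⱼ *cⱼ*·*Lⱼ*(t),

   where *r* is a reference spectrum, *pᵢ* span the paraffin interference
   (bands at 1380 and 1468 cm⁻¹; mean + principal directions of tissue-free
   paraffin measurements), and *Lⱼ* are Legendre polynomials on the axis
   mapped to [−1, 1]. The corrected spectrum
   (*s* − Σ*bᵢpᵢ* − Σ*cⱼLⱼ*)/*m* is de-paraffinized, baseline-free and
   normalized in one step, so sections need no chemical dewaxing. Spectra
   with implausible scale *m*, large residual, or no amide-I band are
   quality-rejected.
2. **Segmentation.** K-means (Lloyd's algorithm, k-means++ seeding, best of
   several restarts) clusters each image's corrected spectra independently;
   clusters are labelled with histology classes (nuclear, cytoplasmic,
   mucin, lamina propria, submucosa, stroma) and rendered as digital stains
   with a Ward dendrogram over the centroids.
3. **Classification.** Epithelial spectra (nuclear + cytoplasmic clusters)
   are projected onto principal components; one-way ANOVA keeps up to 25
   components that separate the pathology groups at the 95% level; linear
   discriminant analysis classifies each spectrum. Leave-one-sample-out
   cross-validation holds out all spectra of one sample per fold — PCA,
   ANOVA selection and LDA are refit from training spectra only — and each
   sample is called by **majority vote**: a class holding >50% of its
   spectra wins decisively.
4. **Evaluation.** Confusion matrices at spectrum and sample level,
   one-vs-rest sensitivity/specificity, overall and balanced accuracy, and
   ROC/AUC (concordance probability) for two-group models.

The synthetic generator builds cohorts of gland-like tissue tiles from
Gaussian bands at the positions above, adds paraffin bands, multiplicative
scatter, polynomial baselines and noise, and returns the ground-truth tissue
maps and contamination coefficients, so every stage can be scored exactly.

## Worked example

```python
from irhisto import synthetic, pipeline
from irhisto.evaluate import confusion, metrics

cfg = synthetic.CohortConfig(samples_per_group=5, tile_shape=(16, 16),
                             seed=11, effect_size=0.35)
result = pipeline.run_pipeline(cfg)   # simulate -> EMSC -> segment -> LOSOCV
cv = result.cv

print(f"epithelial spectra analysed: {len(result.extracted)}")
print(f"pooled per-spectrum accuracy: {cv.spectrum_accuracy:.1%}")
print(f"majority-vote sample accuracy: {cv.sample_accuracy:.1%}")
rep = metrics(confusion(cv, "sample"))
print(f"average sensitivity: {rep.average_sensitivity:.1%}, "
      f"average specificity: {rep.average_specificity:.1%}")
```

prints

```
epithelial spectra analysed: 2129
pooled per-spectrum accuracy: 88.8%
majority-vote sample accuracy: 100.0%
average sensitivity: 100.0%, average specificity: 100.0%
```

At this moderate effect size individual spectra are misclassified ~11% of
the time (mostly epithelial misplacement ↔ adenoma, the clinically hard
pair), but pooling each sample's spectra by majority vote recovers every
sample — the sample-level improvement the method is designed around.

The same chain is scriptable from the shell:

```bash
irhisto simulate --config cohort.yaml --seed 3 --out sim/
irhisto preprocess --in sim/ --out spectra.h5 --seed 3
irhisto segment --in spectra.h5 --sample normal_00 --k 4 --seed 0 \
        --out seg.h5 --stain stain.png --dendrogram dend.nwk
irhisto run --config cohort.yaml --seed 3 --out report/
```

`report/` then holds `metrics.json`, confusion matrices (both levels,
counts and row-percentages), LD scatter data and figures.

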