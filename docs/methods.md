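# Methods

This note documents the models implemented in `irhisto`, their assumptions,
the defaults and why they were chosen, and what the synthetic data do and do
not establish about real tissue spectra.

## Data model

A sample is a hyperspectral absorbance cube indexed (row, column, band),
row 0 at the top, bands ascending in wavenumber, stored in an HDF5 container
(datasets `axis`, `data`; attributes `sample_id`, `pathology`,
`pixel_size_um`). Flat spectra collections carry per-record metadata
(sample, pathology, tissue class, pixel coordinates) and are stored as HDF5
(full precision) or CSV (9 significant digits). The wavenumber axis must be
strictly increasing and uniformly spaced (asserted to 1e-9 relative
tolerance, not silently assumed); any uniform spacing is accepted on input,
and synthetic data use 4 cm⁻¹ sampling over 1000–1800 cm⁻¹ (201 points),
matching the nominal spectral resolution of FPA-FTIR instruments.
Absorbance is the only stored quantity; instrument file formats and
transmittance conversion are out of scope.

## Synthetic tissue generator

The generator emulates the statistical structure the analysis assumes, not
tissue optics.

**Spectra.** Each tissue class has a profile of Gaussian bands at standard
assignments: 1040 (sugars; mucin and cytoplasm), 1078 and 1238 (DNA;
nuclear), 1160 (proteins), 1546 (amide II), 1654 (amide I), 1726
(phospholipids). 1380 and 1468 cm⁻¹ are reserved for paraffin and never
appear in tissue profiles. Widths (8–16 cm⁻¹ SD) and amplitudes (0.05–1.0
absorbance) are fixed defaults chosen to give fingerprint spectra of
realistic shape and magnitude.

**Pathology contrast.** Disease is encoded as amplitude modulation of the
DNA and sugar bands: DNA rises normal < adenoma < epithelial misplacement
< cancer, with epithelial misplacement placed nearest adenoma so those two
groups overlap most at moderate signal; the cytoplasmic sugar band falls
with neoplastic progression but is elevated in epithelial misplacement
(retained intracytoplasmic mucin), which is its main separating feature in
epithelium-only models. A profile stores factors at unit effect; the cohort
`effect_size` e rescales factor f to 1 + e(f − 1), so e = 0 makes all
groups identical and larger e increases separation monotonically (a tested
invariant). There is no quantitative anchor for clinical effect sizes, so
e is a free simulation parameter; the packaged analyses use e = 1.0
("strong", separation far above the within-class spread), 0.35
("moderate", per-spectrum error ≈ 10%) and 0 (null), and state so wherever
they are used.

**Contamination.** observed = scatter · pure + Σ amplitudeᵢ · paraffinᵢ +
Legendre baseline + white noise. Defaults: scatter uniform in (0.7, 1.3),
two paraffin bands (1380 cm⁻¹ SD 9, amplitude 1.0; 1468 cm⁻¹ SD 11,
amplitude 0.8) with independent per-pixel amplitudes uniform in (0.1, 0.6),
baseline degree 2 with coefficient scales (0.05, 0.02, 0.01), noise SD
0.005 absorbance. Noise is i.i.d. Gaussian per channel — the simplest model
sufficient for parameter-recovery testing; correlated detector noise and
resonant Mie scattering are deliberately not modelled. All drawn
coefficients are returned as ground truth.

**Layout.** Non-cancer tiles contain elliptical glands — mucin lumen,
cytoplasmic annulus, nuclear rim — in lamina propria (normal, adenoma) or
submucosa (epithelial misplacement). Cancer tiles contain irregular
epithelial blobs (thresholded smoothed Gaussian fields) in stroma, with
nuclear and cytoplasmic pixels interleaved at random: the lost gland
architecture. Two geometric choices matter for inference and were made
deliberately:

* the nuclear rim and cytoplasmic annulus have equal areas (rim boundary at
  √((1 + 0.38²)/2) of the gland radius), and
* the cancer blob mix probability is drawn from a reference gland layout
  generated by the same process,

so that the nuclear:cytoplasmic composition of extracted epithelium is
identically distributed across pathologies, including pixelation bias. This
guarantees that at effect size 0 the group mean epithelial spectra converge
and a classifier cannot learn pathology from composition alone — without
it, null cohorts scored systematically above chance. Glands that do not fit
the tile are dropped with a logged warning, never an exception. One tile
per sample by default (the emulated acquisitions ranged from 1×1 to 5×6
tiles); default 10 samples per group, 128×128 pixels at 1.1 µm — tests and
the acceptance script use 16×16 tiles to keep LOSOCV runs in seconds, which
leaves ~100 epithelial spectra per sample.

Synthetic tiles are fully covered by tissue, so the quality filter is
exercised by dedicated degenerate inputs in tests rather than by cohort
background pixels.

## EMSC preprocessing

Spectra are truncated to the fingerprint region (closed interval, default
1000–1800 cm⁻¹), then fit by ordinary least squares against the design
[reference | paraffin components | Legendre 0..degree]. Defaults and
rationale:

* **Baseline**: Legendre polynomials on the axis mapped to [−1, 1], degree
  4. Orthogonal polynomials keep the design well conditioned; degree 4
  covers any generator baseline of degree ≤ 4 exactly.
* **Paraffin basis**: the mean of tissue-free paraffin measurements plus
  their first 2 principal directions (the synthetic paraffin model has two
  independently varying bands); configurable for real data. A direction
  with variance at rounding level is flagged with a warning.
* **Reference**: the channel-wise mean spectrum of the dataset, computed
  once upstream of cross-validation. The reference is label-free, so this
  does not leak pathology information into the folds; only PCA, ANOVA
  selection and LDA are refit per fold.
* **Quality criteria**: scale in [0.2, 5], residual RMS ≤ 10× the median
  residual, corrected amide-I (nearest point to 1654 cm⁻¹) ≥ 0.05. All are
  configuration, logged per rejection rule; flat or empty spectra are
  rejected, never raised. |scale| below 1e-3 is a reject signal from the
  correction itself.

**What correction can and cannot recover.** The corrected spectrum is
(observed − fitted interference − fitted baseline)/scale = reference +
residual/scale. When the observation is scale·reference + contamination
within the basis span, recovery and all coefficients are exact (tested to
1e-8 against a normal-equations oracle, recovery to 1e-6 relative L2).
When the spectrum differs from the reference, the component of that
difference lying in the paraffin/baseline span is absorbed into those
coefficients — a distortion inherent to EMSC, common-mode across a dataset
corrected against one reference, and harmless to classification, but the
reason "exact recovery" statements are specific to reference = pure
spectrum.

## Segmentation

Lloyd's algorithm with k-means++ seeding, Euclidean distance on corrected
spectra (EMSC already normalizes; no second normalization), 10 restarts by
default keeping the best within-cluster sum of squares, tolerance 1e-6
relative WCSS change, 300 iterations maximum. The WCSS is asserted
non-increasing at every iteration; empty clusters are re-seeded from the
farthest point; after convergence one final mean update makes every
centroid exactly the mean of its members. `scan_k` scores k = 2..8 by mean
silhouette on a fixed-seed subsample of ≤ 2000 spectra and returns all
candidates — cluster counts on real images are a pathologist's call, and
the automated recommendation is an aid, not an authority. A constant image
has no defined silhouette; k = 1 is recommended with a warning. Cluster
labelling is explicit (YAML mapping) for real data and automated by
ground-truth majority vote only for synthetic cohorts. The centroid
dendrogram uses Ward linkage (a choice; the linkage used for published
dendrograms of this kind is typically unstated) serialized as Newick.

## Classification

* **PCA** by SVD of mean-centered spectra, up to 50 components (at the
  synthetic scale the rank limit usually binds first), signs fixed so each
  loading's largest-magnitude entry is positive.
* **ANOVA screen**: one-way fixed-effects F-test per component score across
  groups; keep p < 0.05, at most 25 components, smallest p first. Scores —
  one value per spectrum per component — are the quantity with per-group
  replicates, hence the test target. If nothing passes (possible under a
  null), the single smallest-p component is kept so the chain remains
  operable.
* **LDA**: class means, pooled within-class covariance with ridge
  1e-6 · trace/dim (guards near-singularity in ≤ 25 dimensions; configurable,
  and a singular covariance with ridge 0 is an error advising a positive
  ridge), equal priors (balanced designs), Gaussian equal-covariance
  posteriors, discriminant directions from the generalized eigenproblem.
* **LOSOCV**: one fold per sample; PCA, selection and LDA are fold-scoped
  by default (a `global_pca` flag reproduces the leaky single-PCA variant
  for comparison — which variant produced published figures of this kind
  is generally unstated). Every fold's training-id set is hashed and
  audited against the held-out id. All spectra of the test sample are
  predicted; the sample is called by majority vote (> 50% decisive;
  otherwise plurality with ties broken by mean posterior, flagged
  non-decisive). An optional per-sample subsample (fixed seed) exists for
  very large cohorts; unused at synthetic scale.

## Evaluation

Sensitivity/specificity are one-vs-rest with the remaining classes pooled;
averages are unweighted over classes. Overall accuracy (trace/total) and
balanced accuracy ((avg sens + avg spec)/2) are both reported because
published "accuracy" figures of this kind are consistent with either
definition. A class with no true instances gets an undefined sensitivity,
reported as missing and excluded from averages with a warning — never
silently zero. AUC is the concordance probability computed from ranks (ties
half-weighted), identical to brute-force pairwise concordance; ROC curves
are reported at spectrum level (pooled held-out posteriors or LD scores)
and sample level (vote fractions). Multi-class ROC is limited to a clearly
labelled one-vs-rest convenience. Report bundles (JSON + CSV + figures) are
byte-deterministic given the same cross-validation result.

## What the tests do and do not show

Passing tests establish that the implementation is correct on data obeying
its own generative assumptions: linear contamination within the EMSC span,
Gaussian bands, i.i.d. noise, and tissue classes that are spectrally
homogeneous. They do not establish clinical performance: the emulated
study's FFPE dataset is not publicly deposited, so its published
percentages serve only as qualitative trend references (majority voting
improving on single-spectrum prediction; epithelial misplacement
overlapping adenoma most), and the cohort analyses here quantify those
trends on synthetic data with stated effect sizes. Known limitations:
no Mie/dispersion artefacts, no correlated noise, no spatial texture within
a tissue class, no multi-tile mosaics by default, and cluster labels on
real data require expert review.

## Problem sizes

Packaged analyses use cohorts of 4 × 10 samples at 16×16 pixels (~100
epithelial spectra per sample after extraction, ~4000 per cross-validation)
and 64×64 images for segmentation scoring; the full test suite runs in
about half a minute and the acceptance script in well under a minute on one
CPU. All sizes are configuration, and the same code paths scale to full
128×128 tiles.
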