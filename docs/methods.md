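# Methods

`memdecode` implements a longitudinal multivoxel-pattern-analysis (MVPA)
pipeline for decoding which of several well-learned autobiographical
memories a subject is recalling from high-resolution fMRI patterns, and
for asking whether the *neural populations* supporting a memory move
over time. Because the kind of data it targets (per-subject 4D BOLD at
1.5 mm, manual ROI masks, repeated cued-recall trials) is rarely
shareable, the package pairs the analysis pipeline with a synthetic
BOLD generator whose ground truth is known exactly, so that every stage
is testable end to end.

## The experimental design being emulated

Nine memories, three per condition (`recent`, `remote`, `control`),
each recalled 14 times for 12 s after a 3 s word cue, with a 1.5 s tone,
two 3 s ratings (vividness, consistency, each 1–5) and 4 s rest per
trial: 126 trials split into two equal scanning sessions of 63, in
pseudo-random order with no memory repeated back-to-back. Acquisition
is 1.5 mm isotropic with TR 3.5 s. Only trials rated ≥4 on *both*
vividness and consistency enter the analysis; ratings are simulated so
that a trial survives this filter with probability 0.79 (matching the
observed ~11 of 14 retained trials per memory). All of these defaults
live in `DesignSpec` and are the package's standing study conditions.

## Synthetic data (forward model)

* **Phantom geometry.** Disjoint ellipsoidal ROI masks with exact voxel
  counts; hippocampus-like masks are elongated 3:1 along a designated
  long axis so that the anterior/posterior split is meaningful.
* **Ground truth.** Each (ROI, study, memory) has a sparse weight map:
  a spatially compact support blob (default 40% of the ROI, settable
  per ROI) with standard-normal weights. Supports are *clustered*
  rather than uniformly scattered because the map-overlap analysis is
  about spatially segregated populations — uniformly scattered
  supports would make all searchlight information maps coincide even
  when the underlying populations are disjoint. A condition's
  memories share one condition centre (individual blobs jittered
  around it); the reference condition's centre sits in the ROI's outer
  quintile, so a condition constrained to avoid it settles at the
  opposite pole, giving the along-the-long-axis segregation the
  overlap analyses probe.
* **Overlap control.** `support_overlap` fixes the fraction of support
  voxels a memory shares with the same-index memory of the first
  condition; the non-shared part is drawn from voxels untouched by the
  first condition, so overlap 0 yields condition-wise disjoint
  representations and overlap 1 identical supports. The same
  construction applied across the two studies (`timepoint_overlap`)
  models a representation that relocates, or not, between timepoints.
  With three or more conditions the later conditions are constrained
  against the first (reference) condition only; pairwise constraints
  among all sets simultaneously are over-determined.
* **BOLD.** Per memory, a recall-period boxcar is convolved with the
  canonical double-gamma HRF (SPM parameters: peak 6 s, undershoot
  16 s, ratio 6; `nilearn`'s `spm_hrf` at 0.1 s resolution) and sampled
  at the TR; a voxel's course is the amplitude-scaled mix of the maps
  it participates in, plus a linear per-session drift (default 0.05
  signal units/volume) and i.i.d. Gaussian noise (default SD 1.0, in
  the same arbitrary units as the unit default amplitude). The
  defaults put cross-validated decoding accuracy in the mid-range
  between chance (1/3) and ceiling at the scaled-down ROI sizes used
  here, comparable to the 35–55% accuracies typical of single-memory
  decoding studies.
* **What is not modelled.** Motion, physiological noise, field
  inhomogeneity, spatial autocorrelation of the noise (beyond what the
  smoothing step induces), anatomical variability, any dependence of
  the ratings on signal quality. Passing tests therefore demonstrate
  the *pipeline's* correctness and calibration, not robustness to real
  scanner artefacts.

## Preprocessing

Fixed order: 3 mm FWHM Gaussian smoothing → per-session linear detrend
(slope removed, session mean retained) → temporal convolution of the
data with the canonical HRF → onset shift → window extraction →
rating filter. Convolving the data (rather than deconvolving via a
GLM) doubles the effective BOLD delay to ~12 s; the compensating shift
is `round(delay / TR)` = 3 whole volumes at TR 3.5 s, and the recall
window spans `ceil(12 / 3.5)` = 4 volumes. The trial's onset volume is
the first volume acquired at or after the onset (ceiling, not floor):
with 26.5 s trial spacing and TR 3.5 s, flooring can slide the window
up to one TR early, into the previous trial's HRF undershoot, which
measurably degrades pattern recovery. The 4 volumes are averaged into
one pattern per trial so each trial contributes a single classifier
sample and temporal autocorrelation cannot leak across folds
(`volumes_as_samples=True` exposes the alternative).

Two residual contaminations of per-trial patterns are inherent to this
pipeline and worth knowing about: the retained session mean is a
positive mixture of all nine maps, and the preceding trial's
(double-convolved) undershoot subtracts a small multiple of its map.
On noiseless data both together bound per-trial cosine alignment with
the planted map at roughly 0.98–0.995 (mean >0.99); they are removed
in practice by the classifier's training-split z-scoring.

## Decoding

* **Folds.** Stratified 10-fold cross-validation over a condition's
  trials (three classes, ~31 retained trials). If the smallest class
  has fewer than k trials, k drops to that count (logged).
* **Searchlight feature selection** (training trials only). Spheres of
  radius 3 voxels, truncated at the ROI border, one centred on every
  ROI voxel. Each sphere is scored by inner 5-fold cross-validated
  ECOC-SVM accuracy (pooled over inner test trials). The fold's
  feature set is the union of all spheres whose score beats chance on a
  one-sided binomial test at α = 0.05. A bare "above chance" rule is
  not usable here: inner scores scatter symmetrically around chance, so
  half of all spheres would qualify in every fold and the selection
  would cover the whole ROI; the significance rule admits ~5% of
  spheres under pure noise while retaining any genuinely informative
  sphere, and reproduces per-fold selected-voxel fractions in the
  tens of percent of the ROI. If no sphere qualifies, the single
  best-scoring sphere is used and the fold is flagged.
* **Classifier.** Error-correcting output codes with one-vs-rest
  dichotomies (codewords are identity rows; minimum pairwise Hamming
  distance 2 for three classes). One linear soft-margin SVM per
  dichotomy (liblinear, C = 1, squared hinge; features z-scored with
  training statistics, making accuracy invariant to affine rescaling
  of the patterns). Test patterns are decoded to the class whose
  codeword is nearest in Hamming distance to the vector of binary SVM
  outputs; ties resolve to the lowest class index for reproducibility.
  For one-vs-rest codebooks the dichotomies are independent liblinear
  subproblems and are fitted in a single multi-class call; the general
  per-dichotomy path handles arbitrary codebooks.
* **Set-level generalisation.** A binary condition classifier trained
  with one memory per condition held out and tested on the held-out
  memories' trials, averaged over all held-out combinations (chance
  1/2). Above-chance accuracy requires a condition-level component
  shared across memories, not memory identity.
* **No cross-study transfer.** Classifiers are never trained on one
  study and tested on the other; studies are compared through their
  per-study accuracies and information maps only.

## Information maps and overlap

A fold's selected voxels form its "voxel set"; the information map is
the union over folds of the sets from folds where selection succeeded
(fallback folds contribute nothing). Overlap between two maps is the
Dice coefficient 2|A∩B|/(|A|+|B|). The permutation null redraws both
maps as uniformly random ROI subsets of the observed sizes (1000
draws): position shuffling preserving only the cardinalities, which are
the only quantities the Dice null depends on (E|A∩B| = ab/N, so the
null mean is ≈ 2ab/(N(a+b))). The group statistic is a two-tailed
one-sample t across subjects on (observed − subject's null mean), with
the direction reported; per-subject permutation p-values are also
returned.

## Group statistics

One-tailed one-sample t against chance (1/3) for each (ROI, condition,
study) cell — only above-chance decoding is of interest; two-tailed
paired t for condition and study contrasts; one-way repeated-measures
ANOVA (subject effects removed, no sphericity correction) for omnibus
comparisons, and a 2×2 within-subject interaction computed as the
squared paired t on difference-of-differences. No multiplicity
correction is applied; reports carry the number of tests run.

## Numerical and degenerate-input conventions

Rounding is half-away-from-zero for the onset shift and half-up for
the anterior slice count; the anterior fraction applies to *occupied*
slices, not the bounding box. Zero-variance inputs to t-tests are
errors, as are empty ROI masks, both-empty Dice masks, classes with
fewer than two trials, and schedules for which no no-immediate-repeat
order exists. All randomness flows from one integer master seed
through named SHA-256-derived substreams (`derive_seed`), so any
result regenerates bit-identically.

## Problem sizes and scale-dependent parameters

The package's own test and calibration runs use scaled-down phantoms —
ROIs of ~36–90 voxels on grids of ~8–26 voxels per side, cohorts of
2–100 subjects — chosen so that full cohorts run on a single CPU in
minutes. Chance level, test calibration and the qualitative contrast/
overlap patterns do not depend on ROI size; absolute accuracies do, so
they are compared against chance and between conditions, never against
the accuracies a 928-voxel hippocampus would give.

Two pipeline parameters are *spatial/statistical scale* parameters and
must shrink with the phantom. A radius-3 searchlight is 13% of a
928-voxel hippocampus but ~half of a 90-voxel phantom ROI, so any
selected sphere covers half the region and no information map can be
spatially selective; likewise the union over 10 folds of α = 0.05
selections accumulates enough false-positive spheres to blanket a tiny
ROI. The map-overlap recovery scenario therefore uses radius 1.5
voxels and selection α = 0.001, scaled to its 90-voxel ROI; the
pipeline defaults remain radius 3 and α = 0.05 for realistically
sized ROIs.

## Known limitations

Condition overlap control is exact only against the reference
condition; the inner-CV sphere scores are exchangeable but not
independent across spheres (shared folds), so the binomial selection
test is approximate; the RM-ANOVA assumes sphericity; the Dice null
assumes exchangeable voxel positions within the ROI, which ignores any
spatial smoothness of real information maps.
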