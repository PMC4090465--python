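# Methods

## Problem and model

A supersecondary-structure motif is two secondary-structure elements
(helix H or strand E) joined by a loop; the four simple classes are HH,
HE, EH and EE. Backbone chemical shifts deviate from random-coil values
in structure-dependent directions (helix raises Cα and C′ and lowers Hα;
strand does the opposite and raises Cβ), so the *average* shift profile of
a motif segment separates the classes to a useful degree.

Each segment is reduced to one feature per selected nucleus: the
arithmetic mean of that nucleus's assigned shifts over the segment's
residues. The classifier is quadratic discriminant analysis: class
*v* is a Gaussian N(μᵥ, Σᵥ) fitted on the training segments of that
class, and a query R is assigned to argmaxᵥ ηᵥ with

    ηᵥ = ln pᵥ − δᵥ/2 − ½ ln |Σᵥ|,   δᵥ = (R − μᵥ)ᵀ Σᵥ⁻¹ (R − μᵥ).

ηᵥ equals the log joint density ln pᵥ + ln N(R; μᵥ, Σᵥ) up to the
class-constant (d/2)·ln 2π, so the argmax is the Bayes rule. Assumptions:
class-conditional Gaussianity of the averaged features, and training
labels that reflect the true motif classes.

### Covariance divisor

Σᵥ uses the population divisor pᵥ, not the unbiased pᵥ − 1. With the
class sizes this tool targets (tens of segments per class) the two differ
by 1–2% of each entry and rarely change a call; the population form is the
package's convention and is what the serialized models store. The
scikit-learn cross-check in the test suite (which uses pᵥ − 1) therefore
asserts near- rather than exact agreement.

### Priors

`prior_mode="count"` puts p = pᵥ in the ln p term; `"proportion"` uses
pᵥ/N. The two differ by the class-constant ln N, so predictions are
provably identical (a tested invariant); count mode is the default, and
proportion mode exists because it is the probabilistically standard
reading.

### Degenerate covariances

A singular Σᵥ (identical training vectors, fewer samples than dimensions,
or linearly dependent features — AAC vectors sum to 1 and are *always*
rank-deficient) gets a ridge of 1e-6 · trace(Σᵥ)/d on the diagonal,
recorded in the model as `regularized`; a hard error is raised only if the
matrix is singular even after ridging. Ties in argmax η are broken toward
the earlier class in the fixed order (HH, EH, HE, EE) and flagged.

## The margin coefficient

The relative margin R = (η_corr − η_wro)/η_corr with cutoff 0.4 measures
how decisively the top score beats the best rival. As defined, it needs
the *true* class (η_corr) and its sign flips when η_corr < 0 (η is a
log-scale quantity and is usually negative). The package therefore
exposes two modes:

* **margin** (default, prediction-time): reference = predicted class,
  denominator |η_top1|; R < threshold only sets a low-confidence flag and
  never changes a label.
* **label_aware** (evaluation-only): a misclassified segment whose R
  relative to its true class is below the threshold is re-counted as
  correct. This uses the true labels inside the score — it is label-
  leaking, is marked as such in logs and reports (`n_corrected`), and is
  provided only so that corrected figures of this kind can be reproduced
  side by side with the honest margin-mode figures. By construction its
  accuracy is never below margin mode's (a tested property).

## Feature extraction with assignment gaps

Real shift files have missing assignments. The per-nucleus mean is taken
over the residues that carry that nucleus (the per-nucleus count is kept
in the vector's `support`), and a segment is excluded from a run only when
a requested nucleus has zero assignments in it; exclusions are reported,
never silent. No re-referencing, outlier filtering or random-coil
correction is applied: shifts are used as given.

## Evaluation

Stratified threefold cross-validation: segments are shuffled within each
class under an explicit seed (default 20140618) and dealt round-robin into
three folds, so every class appears in every fold whenever it has ≥ 3
members (smaller classes are a named error). Each fold is scored against
a model fitted on the other two. SPᵢ is the precision form
TPᵢ/(TPᵢ+FPᵢ), reported alongside the true-negative rate; "average SN/SP"
is the unweighted mean over the four classes, with empty-denominator
classes excluded and reported as NaN. Q_total is computed on the counts
pooled over the three test folds (every segment is tested exactly once);
per-fold values are also listed. The feature-combination experiment draws
one fold assignment on the full segment list and re-uses it for every
nuclei subset and for AAC, so subset scores differ only through the
features (and through any subset-specific exclusions, which keep their
fold indices).

## Synthetic data generator

The generator emulates the statistical shape of a motif benchmark: per
class it draws a latent six-nucleus vector from N(μᵥ, Σᵥ), then each
residue of the segment emits latent + N(0, σ²) noise per nucleus, and
each record is dropped independently with probability `missing_rate`.
Class signal lives at segment level and noise at residue level, matching
the averaging feature map (the variance of the average shrinks as 1/l, a
tested property) and giving tests exact control of separability.

Defaults, chosen once as plausible for backbone shifts: coil baseline
(C 176.0, Cα 55.0, Cβ 38.5, H 8.25, Hα 4.45, N 119.5 ppm) with
helix/strand offsets of the conventional sign and ~1–2.5 ppm (carbons,
nitrogen) / ~0.3 ppm (protons) magnitude; mixed classes average the two
elements with weights 0.62/0.38 so HE and EH stay distinct; diagonal
covariances with SDs ≈ 1.1–1.4 ppm (carbons), 0.25–0.30 ppm (protons),
2.4 ppm (N); segment lengths uniform on 6–16 residues; residue noise
0.5 ppm; 10% missing assignments; class counts 90/89/97/122 (HH/HE/EH/EE),
the composition of the benchmark this tool targets. Sequences are uniform
over the 20 amino acids, so the AAC baseline scores at chance on synthetic
data *by design* — passing tests show the pipeline is correct, not that
real sequences are uninformative. Likewise the generator encodes no real
shift physics (no sequence- or neighbor-dependence, no nucleus-specific
noise), so synthetic accuracies characterize the method under its own
model assumptions, not performance on experimental data.

## Numerical choices

* Log-determinants via `slogdet`; explicit inverse cached per class
  (dimensions are ≤ 20, conditioning is not a concern after ridging).
* Ridge ε = 1e-6·trace(Σ)/d; model round-trips store the (ridged)
  covariance, so reloaded models reproduce η to ~1e-12 relative.
* Parameter-recovery checks run at 5,000 segments/class with generating
  SDs of 0.5 ppm and inter-nucleus correlation 0.3, so the 0.05-ppm mean
  tolerance is ≈ 7 standard errors; covariance entries are compared on
  the σᵢσⱼ scale (5% there equals a 0.05 correlation error), which also
  keeps the criterion meaningful for entries whose true value is small.
* Problem sizes elsewhere (100 random oracle instances × 200 probes,
  1,000 random confusion matrices, 398-segment benchmark-shaped grids)
  keep the full suite and the acceptance script each under a minute on a
  single CPU while leaving the statistical margins above comfortable.

## Known limitations

* NMR-STAR support covers the assigned-chemical-shift loop only, with a
  whitespace tokenizer (no quoted or multi-line values); everything else
  in a STAR file is ignored.
* Residue numbering is taken as-is; shift files and segment coordinates
  must already share author numbering.
* No secondary-structure shift prediction, re-referencing, or PDB/BMRB
  fetching; inputs are local files.
* Per-class Gaussianity of averaged shifts is an approximation; strongly
  non-Gaussian or heteroscedastic real data will degrade the discriminant
  in ways the synthetic tests do not measure.
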