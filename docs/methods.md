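# Methods notes

## Model and assumptions

The pipeline assumes each subject's volume is a parametric SUVr image
already motion-corrected, normalized to a common anatomical space, and
intensity-normalized to a reference region; `covpattern` starts at that
input contract and does none of the upstream image processing. Because
intensity normalization happened in SUVr space, the scaled-subprofile model
applies only one centering step: subtraction of the control-group mean
profile from each log image. We deliberately add **no** within-subject
demeaning and, by default, **no** across-subject voxel demeaning before the
PCA; "variance explained" therefore means total squared SRP mass and the
eigendecomposition is of the uncentered subject covariance. The alternative
(per-voxel demeaning across subjects) is one flag away
(`fit_pca(..., center_columns=True)`).

The decomposition runs as an SVD of the subjects × voxels matrix, which is
exactly the eigendecomposition of the small subjects × subjects covariance
matrix; with ~10⁴–10⁶ voxels and ≤ a few hundred subjects this is the only
sensible route. Eigenvector signs are pinned deterministically (largest-
magnitude loading positive); pattern orientation does not depend on this
choice because regression coefficients absorb signs — orientation is pinned
by the response coding (patient = 1, higher cognition z = better).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| mask fraction | 0.03 | per-subject threshold, fraction of that subject's max SUVr (inclusive ≥) |
| variance target | 0.90 | cumulative variance fraction the retained leading components must reach |
| stepwise direction | bidirectional | forward adds with backward sweeps, under BIC |
| logistic coefficient cap | 20 | box bound on the constrained MLE when classes separate |
| bootstrap replicates | 5000 | subject resamples for voxel-stability CIs |
| CI level | 95% | two-tailed percentile interval; voxels whose CI straddles 0 are dropped |

BIC conventions: logistic −2·logL + k·ln n; linear (profiled Gaussian
variance) n·ln(RSS/n) + k·ln n, k counting the intercept. Additive
constants are fixed across candidate models, so comparisons are exact. A
candidate enters/leaves only on a BIC improvement larger than 1e-9,
ties break to the lowest component index — selection is therefore
deterministic and invariant to candidate ordering.

Separated logistic fits (common at n ≈ 44 with a strong pattern) are
handled by maximizing the likelihood under the box constraint |β| ≤ 20
rather than by clipping an unconstrained fit: the other parameters
re-optimize at the bound, keeping BIC finite, comparable and reproducible.

## Cognition scoring

Per-test z-scores use the control group's mean and *sample* SD (n−1); with
a 10-subject reference, the sample convention is the defensible one. Tests
where higher raw scores mean worse performance (timed tests by default) are
multiplied by −1 after standardization; which endpoints need inversion is a
battery-specific convention, so the inverted set is configuration, not
code. Domain composites are the mean of a subject's *available* test
z-scores in the domain — no imputation; a subject with no test in a domain
gets NaN there, is excluded from models targeting that domain, and the
global score (mean of the four composites) is defined only when all four
are. Domains covered by a single test are allowed with a warning: the
"at least two tests per domain" recommendation concerns battery design,
not the scoring arithmetic.

## Cross-validation and bootstrap choices

Left-out subjects must not influence any training artifact, so every fold
recomputes the common mask, group mean profile, PCA and stepwise model
from its training subjects only; the held-out volume is vectorized on the
*training* mask. In cognition folds the controls are never rotated out —
they exist solely to anchor the mean profile, and the per-fold PCA uses
patient rows only. A held-out volume with a non-positive value inside the
training mask is clamped to the smallest positive training uptake with a
warning; at training time the same situation is an error (no silent
clamping where it could shape the pattern). Folds whose stepwise model is
empty contribute a score of 0 and are flagged rather than aborting.

The bootstrap fixes the common mask and group mean profile at their
original-sample values inside replicates: per-voxel quantiles are undefined
across differing masks, so "pattern determination" is read as the
PCA + selection + reconstruction stage. Disease-pattern resampling is
stratified (class counts preserved, so no replicate loses a class);
cognition resampling is simple within-patient resampling with
constant-response draws redrawn. Empty-model replicates contribute
zero-weight vectors, which widens intervals toward zero — a conservative
bias. Intervals are plain percentile (2.5/97.5), not BCa.

The ROC operating point maximizes Youden's J; among ties the more specific
(higher) threshold wins. AUC is the exhaustive Mann–Whitney pair count
with ties at 1/2.

## What the phantom emulates — and what it does not

`make_phantom_cohort` builds log-uptake as
baseline(v) + δ·1[patient]·D(v) + Σₖ λ_ik·C_k(v) + smoothed noise, then
exponentiates inside an ellipsoidal brain support (background ≈ 0.01 so the
3% mask rule reproduces the support). Effects live in log space so the
pipeline's log transform linearizes them exactly and derived patterns can
be compared to D by cosine similarity. Defaults define the study
conditions: 32³ grid, 10 controls + 34 patients, δ = 0.2, three covariance
modes with loading SD 0.1 each (one drives cognition, two are nuisance
modes — anterior-posterior gradient and left-right asymmetry), smoothed
voxel noise SD 0.001.

Two scale conventions matter. Pattern maps are unit vector norm over the
grid, so δ and τ are norms of whole-brain signals, not per-voxel changes —
a per-voxel regional change of a few log-percent. The voxel-noise default
is set on that same scale so that, as in heavily smoothed and
partial-volume-corrected parametric images, *structured* inter-subject
covariance (the C_k modes and the disease shift) dominates unstructured
residual noise. Cognition composites are the standardized pattern-0
loading plus N(0, 0.5) noise, patients shifted −1 on average; raw test
scores add per-test offsets, scales and noise, with timed tests inverted.

The phantom does not emulate scanner physics (PSF, scatter, partial
volume), anatomical variability between subjects, registration error, or
hemispheric asymmetries of real cholinergic maps. Passing recovery tests
therefore shows the *estimator chain* is correct and leakage-free under
known covariance structure — not that real acquisitions meet the model's
assumptions.

Test and acceptance runs use desk-scale sizes chosen as the package's
default study conditions: 32³ grids, 500 bootstrap replicates (5000 is the
recommended configuration for real analyses), 10–20 seeds for null
calibrations.

## Numerical details and degenerate inputs

- Vectorization is row-major (C order) and identical across subjects; the
  masked round trip is bit-exact.
- SVD components with singular value ≤ 1e−12 × the largest are dropped as
  numerical rank deficiency.
- The linear-BIC RSS is floored at 1e−290 so exact fits stay finite.
- All-zero SRP matrices, empty common masks, single-class responses, zero
  reference SDs and non-positive masked training values are hard errors
  naming the offending subject/test/voxel.
- One integer seed drives each stochastic stage (phantom generation,
  bootstrap resampling) through `numpy.random.default_rng`; identical
  seeds give bit-identical outputs.

## Known limitations

- Stepwise-BIC selection at n ≈ 34–44 retains a ~5–10% per-candidate
  false-inclusion rate; with large candidate pools the selected set often
  contains one spurious component. This is a property of the selection
  rule, not of the implementation.
- LOOCV score distributions are slightly pessimistic under the null (the
  held-out subject pulls the training pattern away from itself), so null
  AUCs center a little below 0.5.
- Bootstrap stability inherits the original sample's fixed noise
  realization; it quantifies resampling stability, not out-of-sample
  replication.
- The package has no multiple-comparison machinery beyond the CI-straddle
  rule, and no k-fold/permutation alternatives to LOOCV.
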