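# Methods

## Setting and model

`uqseg` operates on the output of a *probabilistic* binary segmentation
model: for one patient, M sampled probability volumes p₁ … p_M over a 3D
grid, each sample tagged with an ensemble-member index e ∈ 1..E and a draw
index s ∈ 1..S (M = E·S). Typical sources are a deep ensemble (E = 5,
S = 1) and a Monte-Carlo-dropout ensemble (E = 5 with tens of dropout draws
per member). The posterior predictive foreground probability is the
Monte-Carlo average of the samples; we average draws within a member first
and then members uniformly, which equals the flat mean whenever every
member carries the same number of draws (enforced by the stack container).

Voxels are treated as conditionally independent given the input, so
volume-level entropy quantities are aggregates of voxel-wise binary
entropies.

## The eight uncertainty measures

All entropies are natural-log (nats); probabilities are clamped to
[1e−12, 1 − 1e−12] before logarithms; the voxel-wise mutual information is
clipped below at 0 to absorb floating-point negatives. Every measure is
oriented so that **larger = more uncertain**; "certainty" is its negation.

- **H, EH, I** — the voxel maps aggregated over the volume. The
  aggregation is configurable (`sum` or `mean`) with **mean as the
  default**: entropy totals over a ~3·10⁶-voxel volume are dominated by
  volume size rather than per-voxel ambiguity, and per-voxel means put the
  thresholds on an interpretable scale (a few 10⁻³ nats for realistic
  volumes).
- **CV** — population standard deviation over samples of the predicted
  structure size |G(x,θ)| = #{v : pₘ(v) ≥ 0.5}, divided by its mean. The
  raw-moment form E[g²] − E[g]² is the population variance, hence ddof = 0.
- **SEH** — for each sample, the mean binary entropy of that sample's
  probabilities over that sample's own structure; then the mean over
  samples. A sample with an empty structure has an undefined 1/|G|
  normalizer; it contributes 0 to the outer mean and raises the
  `empty_structure_samples` flag.
- **SH, SI** — SH is the mean of the voxel-wise predictive entropy over
  the *posterior-mean* structure G(x) = {v : p̄(v) ≥ 0.5}; SI = SH − SEH.
  SI can be negative because SH and SEH average over different voxel sets;
  it is stored as computed rather than clipped, since forcing nonnegativity
  would change the definition.
- **R_DSC** — the negative expected Dice between segmentations resampled
  from the model and its own thresholded prediction ỹ = (p̄ ≥ 0.5). The
  expectation is estimated "doubly stochastically": p̄ is already an MC
  average, and each c is drawn voxel-wise independently as Bernoulli(p̄(v)).
  Voxels with p̄ ∈ {0, 1} are deterministic and handled in closed form, so a
  fully confident stack yields exactly −1. The estimator is seeded and
  depends on the stack only through p̄, making it invariant to sample
  order. An alternative reading — drawing whole correlated member
  segmentations instead of voxel-independent Bernoulli fields — is
  compatible with the doubly-stochastic idea but is not implemented; the
  voxel-independent form follows the literal sampling statement
  c ~ p(y|x).

**Degenerate cases** (an empty predicted structure makes CV, SH, SI and
R_DSC undefined) return NaN plus a named flag instead of raising, so cohort
runs never abort; every downstream consumer treats a flagged patient as
maximally uncertain — an empty tumor prediction is itself a reason for
manual review.

## Segmentation quality metrics

- **Surface extraction**: a foreground voxel is a surface voxel iff at
  least one of its six face-neighbors is background *or outside the grid*
  (so masks touching the volume border still have a closed surface).
- **Distances** are Euclidean between voxel centers in physical mm
  (position = origin + index × spacing). MSD is the symmetric average of
  the two directed mean nearest-surface distances. 95HD is the max over
  both directions of the 95th percentile of directed distances, with
  **linear interpolation between order statistics** (numpy's default). The
  percentile convention is not universal across toolkits and can shift
  95HD by a fraction of a voxel; the test suite pins it against a
  brute-force oracle.
- **DSC conventions**: both masks empty → 1.0; exactly one empty → 0.0.
  MSD/95HD are undefined for empty masks and raise at the function level;
  the cohort-level wrapper reports them as infinity when exactly one mask
  is empty.

## Threshold calibration and referral

The link from uncertainty to quality is a patient-level ordinary
least-squares fit of uncertainty on DSC over a calibration cohort; the
threshold τ for a target quality q is the fitted value at DSC = q. The
default anchor is 0.61 DSC, the literature consensus for expert
interobserver agreement on GTVp, which also serves as the
accurate/inaccurate cut in the contingency analysis. Tie rules: certain
iff uncertainty ≤ τ; accurate iff DSC ≥ cut.

Batch referral sorts patients by descending uncertainty (degenerate
patients first, remaining ties broken by patient id for bit-reproducible
curves) and removes them one at a time until ⌈0.10·N⌉ patients remain. The
curve records the mean retained quality after each removal, including the
0-removed point, and its AUC summary is the unweighted mean over all curve
points — the removal grid is the natural one when no threshold grid is
specified. Instance referral instead applies a pre-calibrated τ and
reports the retained count along with the retained mean, since the
retained-set size is not controlled.

Pearson correlations between certainty (−uncertainty) and DSC use the
standard t-transform p-value; no multiple-testing correction is applied.

## Volume handling conventions

- Voxel indices are 0-based; physical position = origin + index × spacing.
  NIfTI volumes are read in stored voxel order; RAS orientation is assumed
  and orientation metadata is not applied (reorientation is out of scope —
  this is a synthetic-first analysis tool).
- CT windowing clips to [−200, 200] HU and rescales linearly to [−1, 1];
  PET z-normalization uses the population standard deviation (the
  difference from the sample convention is negligible at volume scale).
- Resampling is cell-centered: the output preserves the physical extent
  shape × spacing, and output voxel i samples input coordinate
  (i + 0.5)·new/old − 0.5. This makes an integer down-scaling of spacing
  duplicate voxels exactly and is the convention under which masks stay
  binary under nearest-neighbor resampling. Intensities are resampled
  linearly (the choice for input-image resampling when nothing else is
  stated), model outputs and masks with nearest-neighbor.
- Centered crops put the requested voxel at output index size//2 (floor
  tie-break for even sizes) and pad out-of-bounds regions with 0, the
  background value after the normalizations above.
- Masks are written as uint8, probability/intensity volumes as float32.

## The phantom generator

The generator emulates ensembles of probabilistic segmentations, not
images: no PET/CT intensities are simulated. Ground truth is a union of
random ellipsoids (default 6–12 mm semi-axes in a 64³ × 1 mm volume — the
scale of a small GTVp). Each member's probability volume is
logistic(d/softness) of the signed Euclidean distance d (mm, positive
inside) to that member's perturbed copy of the truth:

- **boundary_softness** (default 1.5 mm) sets the logistic length scale —
  the aleatoric knob; softness → 0 gives hard {0,1} samples.
- **member_jitter** (default 1 mm) draws a per-member rigid shift
  (isotropic normal) and adds a low-order random cosine field to the
  distance — the epistemic knob. Draws within a member (S > 1) add a
  weaker cosine field with amplitude 0.5 × member_jitter, emulating
  posterior sampling of a single model; with zero jitter all samples are
  identical.
- **degradation** (mm) models case difficulty: a shared offset of that
  magnitude displaces the whole ensemble from the truth, and the effective
  member jitter grows by 0.5 × degradation, because in real cohorts hard
  cases both fail and split the ensemble. This coupling is what gives
  ensemble-internal measures (CV, MI) their ability to rank patients by
  true DSC on synthetic cohorts.

Per-patient seeds derive from (master seed, patient index) through numpy's
`SeedSequence`, so cohorts are bit-reproducible and patients are
statistically independent. The degradation schedule is recycled across the
cohort.

What passing tests on phantoms do **not** show: real segmentation models
produce spatially correlated, calibration-imperfect probabilities shaped
by image content (e.g. systematic overemphasis of high-uptake PET
regions); phantom ensembles have clean logistic boundaries and isotropic
perturbations. Results here validate the *measures and machinery*, not any
claim about a specific clinical model.

## Study sizes and numerical checks

The test and acceptance workloads use desk-scale problem sizes chosen so
the full suite runs in about a minute: 16³ stacks (E = 3, S = 4) for the
entropy-decomposition identity, 8³ random mask pairs against an all-pairs
brute-force surface-distance oracle, ≤ 12-voxel volumes for the exact
enumeration of the DSC-risk (2¹² outcomes), 40³ paired phantoms (50 seeds)
for the knob-monotonicity checks, and a 60-patient 48³ cohort (E = 5,
degradation 0–10 mm) for the calibration/contingency/referral pipeline.
The acceptance script reproduces that cohort from a user seed and reports
cohort DSC, Pearson(−CV, DSC), the contingency probabilities, referral
AUCs, and the closed-form residuals.

## Known limitations

- Pairwise-Dice ensemble agreement, test-time augmentation and calibration
  post-processing (temperature scaling) are out of scope.
- The entropy family is binary (foreground/background); multi-class
  structures would need a categorical generalization.
- No DICOM ingestion or orientation correction; NIfTI in stored voxel
  order only.
- Referral analyses are metric-generic (DSC, MSD, 95HD) but uncertainty
  thresholds are calibrated against DSC only, matching the primary use.
- Plot generation is left to the caller; the evaluation report and curve
  CSVs contain everything needed.
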