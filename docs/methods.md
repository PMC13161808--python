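# Methods

## Model and procedure

The package implements coordinate-based network mapping: activation foci
from published study contrasts are treated as seeds into a normative
resting-state functional connectome, and the per-contrast thresholded
connectivity maps are aggregated into a network probability map.

The analysis chain per contrast is

    foci → merged 4-mm sphere seed → per-subject seed-to-voxel Pearson r
    → Fisher z = atanh(r) → one-sample t over subjects
    → voxel-level FWE threshold (one-tailed) → binarize

and across contrasts

    binarized maps → per-voxel fraction of contrasts → strict threshold
    (fraction > 0.60) → final network mask.

Statistical assumptions: subject z-values at a voxel are treated as i.i.d.
normal for the one-sample t-test (Fisher's transformation makes this a
good approximation at typical series lengths); family-wise error is
controlled at the voxel level over all defined in-mask voxels. Only the
positive tail is thresholded by default, reflecting the unsettled
interpretation of negative resting-state correlations; the negative tail
is available through the same machinery for sensitivity analyses.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| seed radius | 4 mm (1, 7 mm variants) | sphere around each focus; voxel included when its center is within the radius (inclusive) |
| alpha | 0.05 | voxel-level FWE level |
| FWE method | Bonferroni | `permutation` (sign-flip max-t, ≥1000 permutations) available |
| probability threshold | 0.60 (0.50/0.70 variants) | strict: voxel kept iff fraction > threshold |
| tail | positive | `negative` for the anticorrelation variant |
| band | 0.01–0.1 Hz | ideal rectangular FFT band-pass, bin-inclusive at both edges |
| smoothing FWHM | 6 mm (real data) | separable Gaussian, σ = FWHM/(2√(2 ln 2)), replicate padding |
| FD spike threshold | 0.5 mm | Power's FD, 50-mm rotation radius |
| motion exclusion | 2 mm / 2° | peak translation/rotation QC |

## Design choices where the design was open

* **FWE method.** Voxel-level FWE is implemented as Bonferroni (exactly
  testable, conservative) plus an optional sign-flip max-t permutation
  test as the exact reference. Random-field-theory correction (the SPM
  convention) is deliberately not implemented; absolute surviving-voxel
  counts on real data will therefore be somewhat conservative relative to
  an RFT-based analysis.
* **Strict probability threshold.** A voxel must be connected to *more
  than* 60% of contrast seeds: with 25 contrasts the minimum surviving
  count is 16, with 24 it is 15. The comparison is done on integer counts
  (smallest k with k/n > threshold) so boundary fractions are exact.
* **Talairach conversion.** The inverse of the Lancaster pooled
  `icbm_spm2tal` affine. The choice is isolated in one function so an
  alternative (e.g. the Brett transform) can be substituted.
* **Seed membership and the 1-mm fallback.** Sphere membership is "voxel
  center within radius" (inclusive) — deterministic and grid-independent.
  On a 3-mm grid a 1-mm sphere can capture no voxel center; such a focus
  contributes its single nearest voxel instead, so every focus contributes
  and 1-mm-seed analyses remain meaningful.
* **Seed time course.** Unweighted mean over seed voxels. Correlations are
  clipped to |r| ≤ 1 − 1e-7 before atanh so degenerate voxels stay finite
  (z ≈ 8.4 instead of ∞); zero-variance voxels get z = 0 and are counted
  in the log.
* **Order of operations.** Nuisance regression precedes band-pass
  filtering, then smoothing. Regression residuals are exact least-squares
  residuals (orthogonal to the design); the band-pass is an idempotent
  Fourier projection.
* **Spike handling.** One indicator regressor per FD-flagged volume (no
  volume deletion), keeping the time grid intact for filtering. All-zero
  and duplicate design columns are collapsed with a warning so degenerate
  traces cannot make the design rank deficient.
* **Degenerate alpha.** `alpha = 1` is accepted as an explicit uncorrected
  case (every defined voxel with an effect on the requested tail), useful
  for plumbing tests; ordinary analyses use alpha ∈ (0, 1).
* **Undefined voxels.** Voxels with zero across-subject variance have no
  t-value; they are flagged and can never survive thresholding.

## The phantom generator

`fcnm.synthetic` emulates exactly the statistical structure the analysis
assumes: each planted network n has one latent time course L_n(t) — unit
variance white noise low-pass filtered below 0.1 Hz so the preprocessing
band-pass does not remove it — and every member voxel observes
sign_n · snr · L_n(t) + ε(t) with i.i.d. unit Gaussian ε. Latents are
drawn per subject (connectivity is a within-subject quantity), networks
are pairwise disjoint by construction, and foci are sampled at voxel
centers inside their network. Under this model the within-network voxel
correlation is r = snr²/(1+snr²) (0.5 at snr 1), the closed form the
oracle tests check. Motion traces are slow Gaussian random walks
(0.02 mm / 0.0002 rad steps) plus optional 1-mm step displacements at
random volumes, which deterministically exceed the 0.5-mm FD spike
threshold while keeping peak motion inside the 2-mm QC bound.

What the phantom does **not** emulate: hemodynamic response shape,
physiological (cardiac/respiratory) noise, spatial autocorrelation of the
noise, registration error across subjects, scanner drift, or partial
voluming. Passing phantom tests therefore demonstrates the correctness of
the computational chain and its calibration under the stated model — not
performance on real data, where effect sizes and noise structure differ.

### Preprocessing configuration for phantom runs

Phantom validation runs use the full regression/filtering machinery with
two deliberate differences from the real-data defaults:

* **No global-signal regression** (and no WM/CSF terms — the phantom has
  no tissue compartments). With a small number of planted networks in
  spatially white noise, the phantom's global mean is essentially a clean
  copy of the planted latent itself (noise averages away over ~2.7·10⁴
  voxels); regressing it out would subtract the very signal the phantom
  plants. In real data the global signal aggregates many vascular,
  respiratory and neural sources, so the default for real runs keeps it.
* **No spatial smoothing.** Smoothing exists to absorb inter-subject
  registration error, which the phantom does not have. On a phantom it
  both blurs the sharp planted boundary and strongly reduces the variance
  of the (spatially white) noise, so boundary voxels just outside the
  planted network acquire detectable leaked signal and the recovered mask
  dilates by a voxel shell — an artifact of smoothing a white-noise
  phantom, not of the mapping statistics. Smoothing correctness is
  verified separately against a discrete-convolution oracle.

### FWE calibration on null phantoms

The null calibration simulates pure-noise subjects, seeds a single 4-mm
sphere, runs the FC → t → FWE chain, and counts repetitions with any
surviving voxel **outside the seed mask**. The seed voxels themselves are
excluded from the count because the seed course is their own average: a
seed of k voxels correlates with each member at r ≈ 1/√k even in pure
noise, so those voxels survive by construction and are true positives of
the experimental design rather than false positives of the threshold. The
Bonferroni denominator still counts all defined voxels (slightly
conservative).

## Problem sizes

The validation experiments run at deliberately reduced, fixed sizes chosen
as desk-scale stand-ins for the full analysis: recovery uses 40 subjects ×
200 timepoints on a 30³ 3-mm grid (10 contrasts × 3 foci, snr 1, planted
radius 24 mm); FWE calibration uses 100 repetitions × 20 subjects × 120
timepoints on a 15³ grid; the negative-connectivity variant uses 12
subjects on a 20³ grid with two antiphase 12-mm regions sharing one
latent. All randomness flows from explicit integer seeds, and identical
seeds reproduce outputs bit-for-bit (NIfTI payloads included).

## Known limitations

* Bonferroni is conservative relative to random-field or permutation
  thresholds; real-data voxel counts will differ from RFT-based analyses.
* No meta-analytic weighting of contrasts (sample size, number of foci):
  each contrast contributes equally to the probability map.
* No covariate-adjusted group model (age/sex), no cluster-extent or TFCE
  correction, no surface-space (CIFTI) support.
* The grey-matter analysis mask for real data is user-supplied; no default
  template mask ships with the package.
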