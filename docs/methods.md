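# Methods

## Design being analyzed

Each subject (a rat in the motivating paradigm) contributes two coregistered,
skull-stripped uptake volumes on a common grid: one accumulated during a PPI
startle session and one during a background-noise control session, plus a
startle-response trial table. Because FDG uptake integrates over the whole
session, there is no within-subject time series; all connectivity statements
are **across-subject** covariances of the task-minus-control uptake change.
The pipeline assumes volumes are already registered to one space — it checks
shape, voxel size (default 0.38 × 0.38 × 0.82 mm) and a space tag, and
refuses mismatches rather than attempting registration.

## Behavioral scoring

A session schedule holds a habituation block (25 startle stimuli by default)
and a main block of 30 trials per stimulus type: control, startle-alone, and
prepulse-alone plus prepulse+startle at each of the 68/72/78/84 dB SPL
prepulse levels — 300 main trials. Inter-stimulus intervals are drawn
i.i.d. uniform on 3–13 s (the distribution is a config choice; a uniform
draw has mean 8 s, and no alternative distribution is implied by the
stated range, so uniform is the default).

Response amplitudes are baseline-corrected integrals over the 100 ms window
starting 5 ms after startle onset. Amplitudes are carried in the
*mean-amplitude* convention (integral divided by window length, in mV) so
that the absolute 30 mV startle-event threshold applies directly; the raw
integral convention is available in `integrate_amplitude`.

Event classification is per trial: a startle-alone trial with amplitude
strictly above 30 mV is a startle event; a prepulse+startle trial is scored
by its per-trial PPI% computed against the session-mean startle-alone
amplitude — strictly below 15% a startle event, strictly above 15% a PPI
event, exactly 15% (or exactly 30 mV) no event. The denominator is the
main-block session mean by default and can be supplied explicitly
(`a_startle_alone=`), which also covers designs where the reference
amplitude comes from a separate block. Habituation trials never enter the
event counts. PPI effectiveness is (n_PPI − n_startle)·100/(n_PPI +
n_startle), undefined when no events were scored.

## Image preparation

Ratio normalization divides every voxel by the mean uptake over the
reference region, implemented as plain division (the output's reference
mean is exactly 1, and the operation is idempotent). This cancels any
per-subject global scale — injected dose, body weight, scanner gain — which
the test suite verifies to machine precision. The reference region must be
condition-independent for the difference images to be interpretable; the
phantom enforces this by construction.

Difference images are task − control on the normalized volumes (a
`background_minus_ppi` flag flips the sign convention, which flips the sign
of every downstream correlation). Smoothing is a separable Gaussian
specified by physical FWHM (sigma_voxels = FWHM/(2√(2 ln 2)·voxel_size) per
axis, so anisotropic voxels get an isotropic physical kernel), with
nearest-edge replication at the boundary to avoid rim artifacts inside
tight brain masks. The paired t-test runs on the unsmoothed normalized
pairs; correlation analyses use the smoothed (1.5 mm FWHM) difference
images; both policies are config switches. Seed values are extracted from
the smoothed difference images by default (unstated in the motivating
design; exposed as `smooth_seed_extract`).

## Group statistics

* Paired t: t = mean(d)/(sd(d)/√n), df = n−1, positive t ⇔ higher uptake
  during the task.
* Behavior correlation: per-voxel Pearson r between difference values and
  PPI effectiveness; companion t = r√(n−2)/√(1−r²), df = n−2.
* Seed connectivity: the covariate is the subject's seed-mean difference
  value; voxels inside the seed are reported but flagged (partial
  self-correlation).

Voxels with zero variance across subjects get t = 0 / r = 0 instead of NaN
and are counted in a QC field, keeping maps total over the mask. Both signs
are always retained. Uncorrected display thresholds use the exact
t-distribution relation; at n = 19, α = 0.05 two-sided the critical |r| is
0.4555 (two-decimal display cut 0.45 — note the displayed value truncates,
it does not round).

## TFCE and permutation inference

TFCE(v) = Σ over h ∈ {δ, 2δ, …, ≤ t(v)} of e(h)^E · h^H · δ, with e(h) the
extent of the connected component containing v at threshold h. Defaults
H = 2, E = 0.5, δ = 0.1, 26-neighbour connectivity (6/18/26 selectable;
26 is common volumetric practice and is not dictated by the design).
Negative lobes are enhanced on the negated map and returned negative;
|t| < δ receives 0; a height exactly equal to a multiple of δ is included
(a 1e−12 tolerance guards float representation of the δ ladder). The
production implementation (per-threshold labeling with vectorized
component accumulation on the bounding box) is tested against a naive
three-loop reference on random maps at all connectivities.

Family-wise error is controlled by the max-statistic method. For
correlation maps the covariate is permuted across subjects (the standard
exchangeability reading for this design); for the paired contrast,
per-subject difference images are sign-flipped (optionally exhaustively for
small n). Each permutation records the image-wide max |TFCE|, so positive
and negative observed lobes are tested against a common two-sided null.

**Threshold convention.** The observed dataset is counted as a member of
the permutation family: a voxel is significant when its |TFCE| strictly
exceeds the j-th largest of the n_perm null maxima, j = floor(α·(n_perm+1)).
Its permutation p-value (1 + #{null ≥ value})/(n_perm + 1) is then ≤ α, so
the family-wise error is controlled at α exactly (for n_perm = 1000,
α = 0.01 this is the 991st order statistic). The alternative convention
⌈(1−α)·n_perm⌉ — the 990th — excludes the observed dataset from the family
and is measurably anti-conservative at moderate n_perm (true FWER
3/(n_perm+1) at n_perm = 200); the calibration experiment below was the
deciding argument. When α·(n_perm+1) < 1 no voxel can reach level α; the
overall maximum is used as the most conservative interpolation-free cut.

## Phantom generator

The phantom emulates the two-condition, 19-subject design on a 40×40×24
grid (voxel 0.38 × 0.38 × 0.82 mm; the brain box holds 18 432 voxels,
matching the scale of a rat-brain mask at this resolution). Eleven disjoint
9×9×6 regions (axis-aligned blocks by default; inscribed ellipsoids
optionally) form: a reference region, two null regions, and three networks —
**lateral** (3 regions incl. a seed), **medial** (3 regions incl. a seed)
and a deactivated **dmn** (2 regions incl. a seed). Blocks of this size
keep the 1.5 mm smoothing halo (~2 in-plane voxels) small relative to each
region, which matters for overlap scores: the significant cluster of a
perfectly recovered network necessarily includes the halo, bounding Dice
away from 1.

Per subject s and network N, the task volume adds
sign_N · amp_N · (1 + w·k_{N,s}) inside N's regions (sign −1 for dmn,
amp defaults 8 on a baseline of 100, w = 0.5, k standard normal i.i.d. per
network). Control and task volumes get i.i.d. voxel noise (sd 2) and a
shared per-subject global scale (lognormal, sd 0.15 in log) that ratio
normalization must cancel. The true behavioral covariate is
(k_lateral − k_medial)/√2 plus N(0, 0.4²) noise, so it correlates
positively with the lateral and negatively with the medial factor; at these
defaults voxel-level |r| with the covariate lands around 0.6–0.8 at n = 19 —
detectable but not trivial.

Matched startle sessions draw startle-alone amplitudes lognormal (median
60 mV, σ = 0.3). On each prepulse+startle trial the prepulse takes effect
with probability 0.1 + 0.8·Φ(z_s) (z the standardized true covariate),
suppressing the response by U(0.4, 0.9); ineffective prepulses leave
|N(0, 0.05)| inhibition. These values were set so that (i) scored
per-animal event counts (~81 PPI / ~68 startle) fall in the empirically
plausible range for a 175-scorable-trial session, and (ii) scored
effectiveness is rank-correlated with the true covariate at Spearman ≥ 0.8
across the cohort (observed ~0.85–0.95 over seeds). Overriding the
attenuation probability to 1 with full suppression (and sub-threshold
startle-alone amplitudes) drives effectiveness to +100; probability 0 with
no residual inhibition drives it to −100.

What the phantom does **not** model: anatomical geometry, PET count
statistics (Poisson projection noise, scanner PSF), partial-volume effects,
registration error, or spatially correlated physiological noise. Passing
recovery tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated covariance model, not robustness to
real-scanner artifacts.

## Experiment sizes and numerical choices

* FWER calibration: 200 Monte-Carlo null phantoms on a 16×16×10 grid
  (n = 19, n_perm = 200, α = 0.01); the grid is reduced because calibration
  depends on exchangeability, not on image size.
* Recovery: default 40×40×24 phantom, n_perm = 1000, α = 0.01.
* TFCE oracle equivalence: 50 random 12³ maps across all connectivities,
  agreement required to 1e−9.
* Zero-variance voxels → statistic 0 (flagged); constant covariates and
  non-positive reference means are errors, not NaNs; permutation tests
  require ≥5 distinct covariate values.
* All stochastic stages derive independent streams from one root seed
  (`numpy.random.SeedSequence`); identical config + seed reproduces every
  output bit-for-bit.

## Known limitations

* No image registration: inputs must share a grid and space tag.
* Connectivity is across subjects; nothing is inferred about within-subject
  temporal dynamics.
* The permutation null for seed maps treats the seed covariate as
  exchangeable across subjects; alternatives (permuting voxel data,
  re-pairing conditions) are not implemented.
* Cluster tables report coordinates in grid mm only; no atlas labeling.
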