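# Methods

`eegaec` implements a source-space EEG functional-connectivity analysis
built around orthogonalized amplitude-envelope correlation (AEC), together
with a synthetic-cohort generator that makes every stage testable against
known ground truth. This note records the models, the defaults and why
they were chosen, and what the simulations do and do not demonstrate.

## The connectivity measure

For each frequency band (theta 4–8, alpha 8–12, beta-1 13–17, beta-2
18–24, beta-3 25–30, gamma 30–100 Hz), ROI timeseries are

1. band-pass filtered with a zero-phase 4th-order Butterworth filter
   (applied forward–backward; zero phase keeps envelope timing intact);
2. jointly replaced by the closest (Frobenius-norm) set of mutually
   orthogonal signals — *symmetric orthogonalization*.  Instantaneous
   signal shared across ROIs is the signature of volume conduction and
   inverse-solution leakage, and a zero-lag-orthogonal set cannot carry
   it.  The correction treats all ROIs symmetrically instead of
   privileging a seed region;
3. converted to amplitude envelopes, |x + i·H(x)| with H the Hilbert
   transform (magnitude, not squared power);
4. Pearson-correlated per ROI pair after discarding 1 s at each end
   (filter and Hilbert edge transients).  By default one correlation is
   computed over the whole record; a windowed mode (non-overlapping
   windows, correlations averaged) is available but off by default — with
   stationary synthetic data the full-record estimate has strictly lower
   variance, and no principled window length presents itself.

The orthogonalization solves `min ||M - O||_F` over matrices `O` with
mutually orthogonal rows by alternating (a) the orthonormal polar factor
of the column-scaled matrix with (b) per-row least-squares magnitude
refitting, to a relative tolerance of 1e-9 (cap 200 iterations).  The
polar factor is computed through the eigendecomposition of the small
n_rois × n_rois Gram matrix, so cost is linear in record length.

Two practical choices sit on top of the textbook procedure:

* **Row normalization inside `aec`.**  The closest-orthogonal fit weights
  rows by magnitude, but reconstructed ROI amplitudes are arbitrary
  (they depend on source depth and regularization), and AEC itself is
  scale-free.  `aec` therefore normalizes each band-limited row to unit
  power before orthogonalizing, which makes the result exactly invariant
  to per-row rescaling.  The public `symmetric_orthogonalize` keeps the
  magnitude-fitting semantics.
* **Degenerate rows.**  A row that is numerically a linear combination of
  the others is *entirely* shared signal; the strict function raises (the
  closest orthogonal set is not unique there), while the pipeline's
  leakage correction zeroes such rows and reports AEC 0 for them —
  nothing of the signal survives the correction, so there is no envelope
  co-variation left to measure.

**Known limitation (signal splitting).**  Symmetric orthogonalization of
two *near*-duplicate channels splits the shared signal roughly equally
between them (the Frobenius-closest orthogonal pair to two nearly
parallel signals straddles them at ±45°), so each keeps about half the
shared power and a residual envelope correlation of ~0.15 remains for a
two-channel near-copy at in-band SNR ≈ 10.  Only pairwise
regression-style orthogonalization removes this entirely, at the price of
asymmetry between ROIs.  The exact-copy limit is clean (AEC 0), and with
four ROIs mixed through a well-conditioned lead field the residual is
far smaller, but users should not expect orthogonalized AEC of
deliberately duplicated channels to vanish.

## Source reconstruction

The inverse is a Tikhonov-regularized minimum-norm estimate with a
diagonal noise model: per-channel variances are estimated from the
recording itself (flatlined channels are floored to the smallest positive
variance and flagged), the data are whitened by `C^{-1/2}`, and

    K = G' (G G' + λ² I)^{-1} W,   G = W L.

Identity source covariance, no depth weighting: with a toy lead field
there is no depth to compensate.  `λ² = 1/9` by default — the common
whitened-SNR = 3 convention — and configurable; reconstruction quality is
insensitive to a factor of a few around it on well-conditioned toy lead
fields (reconstruction–truth correlation > 0.8 per ROI at sensor SNR 10).

Unconstrained three-orientation sources are collapsed to one timeseries
by the first principal component of the 3 × samples block.  PCA preserves
the oscillation's phase, which the Hilbert envelope needs; taking the
vector norm would rectify the signal and double its frequency.  The sign
is fixed by positive correlation with the largest-variance component.
ROI timeseries are sign-aligned means of member sources (each member is
aligned to the ROI's first principal component before averaging, so
anti-phase members reinforce rather than cancel).

## Statistics

* **Group contrast.**  Per (pair, band) cell, a two-tailed permutation
  test on the Welch t statistic: pooled values are re-split into the
  original group sizes `n_perm` times (default 10 000, seeded), and
  p = (1 + #{|t*| ≥ |t|}) / (1 + n_perm) — the add-one estimator keeps p
  valid and never zero.  Welch rather than pooled-variance t because the
  cohort-description tests also use unequal-variance t (their fractional
  dfs reproduce only under Welch).  One permutation schedule is shared
  across the 36 cells, which preserves per-cell validity and the joint
  null ordering.  t > 0 means controls > patients.
* **Multiplicity.**  Benjamini–Hochberg step-up over all 36 pair × band
  cells at q = 0.05; the reported threshold is k·q/m at the largest
  qualifying rank k (0.00556 at rank 4 of 36).  An uncorrected p < 0.01
  mask is reported alongside.
* **Clinical associations.**  AEC values are bounded and typically
  skewed, so Pearson correlations with clinical covariates are tested by
  Monte-Carlo permutation of the covariate, two-tailed, BH-corrected
  across the covariate family; an OLS model of episodes on AEC plus
  age/sex/education/severity (categoricals dummy-coded, first level
  dropped) reports the overall F with (k, n−k−1) df, flagging the
  degenerate perfect-fit case instead of printing an infinite F.
* **Cohort description.**  Welch t (with Welch–Satterthwaite df) directly
  from per-group mean/SD/n, and Pearson chi-square for contingency
  tables, with Yates continuity correction on 2×2 tables by default —
  the convention that reproduces standard reported values for small 2×2
  sex tables (e.g. 0.12 where plain Pearson gives 0.48).  Questionnaire
  group sizes are explicit parameters; n = (20, 18) reproduces the
  fractional dfs of the reference cohort table.

## Classification

A soft-margin SVM with Gaussian kernel
`k(u,v) = exp(-||u-v||² / (2·scale²))`, box constraint C = 3,
kernel scale 1, no standardization (both configurable), evaluated by
leave-one-out cross-validation on the four sgACC–DLPFC AEC features of
one band (beta-1 by default).  Decision-function ties break toward the
control class.  The quadratic program is solved by scikit-learn's SVC
(tolerance 1e-6); the harness — fold construction, determinism, metrics —
is this package's responsibility.

Note that LOOCV with balanced groups is pessimistic under the null: each
training fold's majority class is the held-out subject's wrong class, so
label-shuffled baseline accuracy sits *below* 50 % — a few points below
for well-scaled features (measured ≈ 0.46 on unit-variance features at
n = 40), and near 0 % in the degenerate limit.  That limit is actually
reached on raw AEC features at the default kernel scale of 1: feature
distances are ~0.1, the Gaussian kernel is nearly constant, and without
label signal the SVM collapses to a majority vote, which LOOCV scores
almost always wrong.  With true labels the same configuration classifies
well (the margin parameter C = 3 still lets the small kernel differences
carry the planted separation).  Baselines are therefore compared as "at
or below chance", and planted-separation performance is measured as the
margin over the shuffled baseline, not against a nominal 0.5.

## The synthetic generator

Per subject, each ROI source is a sum over bands of unit-variance
band-limited Gaussian carriers, amplitude-modulated by slow shared
modulators:

    x_i(t) = Σ_b (1 + depth · e_i^b(t)) · c_i^b(t).

Modulators are white noise low-passed at 1 Hz (envelope dynamics are
slow), standardized, and correlated across ROIs by the Cholesky factor of
the planted correlation matrix; `e` is clipped so `1 + depth·e > 0.05`
(no carrier sign flips).  AEC measures envelope co-variation, so the
modulator correlation ρ is the natural coupling dial; the *measured*
ground-truth AEC (the "oracle": band-pass, Hilbert envelope, Pearson on
the noiseless sources) is attenuated well below ρ because the carriers'
own Rayleigh-like envelope fluctuations are uncorrelated noise on top of
the shared modulation (≈ 0.24 at ρ = 0.7, depth 0.5).  Ground truth is
always the oracle value, never ρ itself.

Sources reach the sensors through a toy lead field — spatially smoothed
Gaussian random topographies, unit-norm columns, condition number < 100 —
plus white sensor noise at a chosen power SNR (default 5).  Defaults
mirror a two-group resting-state study: 20 subjects per group, 128
channels, 512 Hz, 360 s eyes-closed-style continuous recordings; the
planted group difference is confined to the beta-1 sgACC_L–DLPFC_R cell
(controls ρ = 0.7, patients ρ = 0.2, all other couplings zero).

The "episodes" covariate is generated from each patient's own
ground-truth AEC at the planted cell:
`episodes = round(max(1, 10 − 25·AEC + ε))`, ε ~ N(0, 1.7²).  The slope
is negative — lower connectivity, more lifetime episodes — and the noise
scale was calibrated once so the planted correlation is strong
(mean r ≈ −0.72 across replicate cohorts at the reduced study scale);
controls carry zero episodes.  Age, sex, education and a severity score
are drawn from plausible marginals and are independent of connectivity
by construction, so adjusted models should (and do) leave the
episodes–AEC association intact.

**What the simulations do not emulate:** real head geometry and depth
dependence, non-Gaussian and nonstationary artifacts (blinks, muscle,
line noise beyond an optional notch target), 1/f background spectra,
inter-subject anatomical variability, or any true disease process.
Passing the planted-recovery studies shows the pipeline's statistical
machinery is sound and unbiased under its own assumptions — not that the
effect sizes or classification accuracies transfer to patient EEG.

## Validation studies and problem sizes

`eegaec.evaluation` packages the Monte-Carlo studies used for
validation, all reduced in scale so they run in minutes on one core:

* null calibration of both permutation tests: 1000 replicate draws,
  n = 20 per group, 499 permutations;
* family-wise null rate of the 36-cell BH-FDR contrast: 200 full
  replicate studies at 16 s / 256 Hz / 10+10 subjects / 8 sensors, with
  identical coupling in both groups;
* planted-deficit recovery: 50 full replicate studies at 60 s / 256 Hz /
  20+20 subjects / 32 sensors — detection rate of the planted cell (top
  |t| and FDR-flagged), LOOCV accuracy vs a label-shuffled baseline, and
  the recovered episodes–AEC correlation.

The recording lengths are deliberate: 60 s at a 1 Hz modulator cutoff
gives ≈ 60 independent envelope observations, enough for the planted
difference (≈ 0.18 in AEC units) to be detected with near-certainty at
n = 20 per group while keeping 50 end-to-end replicates affordable.

## File formats

Recordings are EDF (a built-in 16-bit writer with one-second records and
a shared symmetric physical range; reading via mne, with optional 1 Hz
high-pass and 50 Hz notch at ingestion).  Lead fields and ROI
definitions are JSON; cohort tables CSV; connectivity tensors long-format
TSV (subject, roi_a, roi_b, band, aec); statistical outputs TSV + JSON.
Every output carries the run-configuration hash, all randomness derives
from one master seed, and files are written atomically (temp file, then
rename), so a rerun with the same configuration is byte-identical.
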