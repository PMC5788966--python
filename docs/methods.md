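# Methods

`nirsdecode` implements an offline analysis for decoding a binary engagement
state (high-demand "manual" vs. low-demand "auto" flight phases) from
two-wavelength fNIRS recordings, together with a synthetic-session generator
that provides ground truth for every stage. This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic studies do and do not show.

## Experimental structure assumed

One subject's session consists of 8 landings — 4 per condition, in
pseudo-random order — recorded on a 42-channel montage (6 regions of
interest, 7 channels each: frontal left/central/right, occipital
left/central/right) at 7.8125 Hz with 760/850 nm wavelength pairs at 3 cm
source-detector separation. Landing durations are drawn from a truncated
normal (mean 152 s, sd 22 s, floor 120 s); the floor guarantees that 12
epochs fit into every landing, so each subject contributes 12 x 8 = 96
epochs.

## Synthetic-session generator

The generator is first-class, tested code. It emulates the statistical
structure the analysis assumes, not a biophysical head model.

**Hemodynamics.** Each ROI receives a latent source built from band-limited
Gaussian noise in the low-frequency-oscillation (LFO) band (0.06-0.12 Hz,
80% of latent variance) plus a 1/f pink-noise floor (20%). Inter-ROI
coupling is imposed by mixing independent standardized sources through the
Cholesky factor of the condition's target correlation matrix; this
reproduces any positive-semidefinite coupling matrix in expectation (for
non-PSD inputs the matrix is eigenvalue-clipped and row-renormalised, or
rejected if clearly invalid). Per channel,

    HbO = a_LFO * latent_ROI + offset(condition) + nuisance + noise,

with `a_LFO` = 0.3 uM, channel noise sd 0.1 uM, and global nuisance
sinusoids at 1.1 Hz (cardiac, 0.05 uM), 0.25 Hz (respiration, 0.1 uM) and
0.1 Hz (Mayer wave, 0.1 uM) with per-landing random phases. HbR is the
anti-correlated counterpart, `HbR = -0.5 * (HbO - noise) + noise_HbR`
(sd 0.05 uM), so with all noise amplitudes at zero corr(HbO, HbR) = -1
exactly.

**Condition contrast.** The two conditions may differ in (a) the inter-ROI
coupling matrix (default: uniform 0.75 for manual vs. 0.25 for auto) and
(b) a constant HbO activation offset (default +0.3 uM for manual). The two
contrasts can be zeroed independently; `null_config()` removes both for
null testing. Note that a *constant* offset is largely invisible to the
analysis by construction: optical densities are referenced to the per-epoch
mean and high-passed, so the offset contrast mainly probes that the
pipeline does *not* hallucinate oxygenation differences — the decodable
signal travels through the connectivity features. This mirrors the
motivating finding that connectivity outperforms amplitude-based features
for sustained (non-event-locked) states.

**Forward model and artifacts.** Concentrations are mapped to optical
density through the same modified Beer-Lambert (MBLL) constants the
inverse uses (single source of truth), so the round trip is exact up to
filtering. Motion artifacts are injected in OD space: exponentially
decaying spikes (decay 0.5 s, amplitude 0.02-0.08 OD, 1/min) and step
baseline shifts (0.005-0.02 OD, 0.2/min), both recorded in the ground
truth. Intensities are `baseline * 10**(-OD)`.

**What the generator does not emulate:** photon transport and partial
volume effects, skin blood flow, serially correlated artifact bursts,
habituation/drift across landings, and any realistic spatial falloff of
coupling with distance. Passing tests therefore demonstrate that the
pipeline recovers the *assumed* structure, not that it will reach any
particular accuracy on real recordings.

## Preprocessing

Each landing is segmented into 200-sample (25.6 s) epochs with onsets 60
samples apart; the epoch count per subject is capped by the minimum over
that subject's landings and by a configurable per-landing maximum
(default 12, reproducing the 96-epoch design). Every epoch is processed
independently, which keeps the method compatible with online use:

1. **Optical density**: OD = -log10(I / I_ref) with I_ref the per-epoch
   mean intensity.
2. **Wavelet artifact correction**: db2 discrete wavelet transform at
   maximal dyadic depth; within each detail level the coefficients outside
   [q1 - 1.5 IQR, q3 + 1.5 IQR] are zeroed. Two adaptations make the rule
   behave on 200-sample epochs: the signal is extended by slope-preserving
   (antireflect) padding — periodic extension manufactures an edge jump
   whose coefficients the rule then deletes — and levels holding fewer
   than 8 coefficients are passed through, because quartiles estimated
   from 3-6 values are meaningless and would clip genuine low-frequency
   signal. On a clean sinusoid the correction is a no-op; a 10-sigma
   single-sample spike loses >80% (typically ~90%) of its amplitude.
3. **Band-pass**: Butterworth high-pass 0.01 Hz (order 3) then low-pass
   0.5 Hz (order 5), applied forward-backward (zero phase) by default; a
   causal mode exists for online processing. The stated orders are the
   design orders of the underlying filters; zero-phase application squares
   the magnitude response.
4. **MBLL inversion**: per time point the 2x2 system
   dOD(l) = [eps_HbO(l) dHbO + eps_HbR(l) dHbR] d DPF(l) is solved
   exactly. Extinction coefficients ship as a versioned CSV (Gratzer/Prahl
   compilation, 1/(M cm)); DPF defaults are 6.4 (760 nm) and 5.75 (850 nm),
   both overridable. The inverse is linear and invariant to consistent
   wavelength reordering.
5. **Kept window**: time-domain features use the central 80 samples
   (indices 60..139). Time-frequency transforms are computed on the full
   200-sample epoch and cropped to the same 80 central time points
   afterwards, keeping wavelet edge effects out of all averages.

## Features

**Oxygenation (7 per channel and chromophore):** peak (signed maximum),
mean, variance, skewness, kurtosis, area under the curve (sum of absolute
values — the plain sum, not a trapezoid), and the least-squares slope
against time in seconds. Moments use the population (1/N) convention
inside the ratios; kurtosis is non-excess (Gaussian -> 3). A zero-variance
window makes skewness/kurtosis NaN; downstream, non-finite feature
*dimensions* are dropped with a warning — epochs are never dropped.

**Connectivity (5 per channel pair and chromophore):** covariance
(divisor N-1; correlations are divisor-invariant), Pearson, Spearman
(Pearson on average ranks), Welch magnitude-squared coherence, and Morlet
wavelet coherence. The two coherences are averaged over the closed band
0.078125-0.3125 Hz (periods 3.2-12.8 s), the LFO band the connectivity
literature targets.

*Welch estimator*: Hamming taper, 100-sample segments, 50% overlap — K = 3
segments on a 200-sample epoch. K = 1 is refused because the estimator is
then algebraically 1 at every frequency. Under independence the estimate
has mean 1/K per bin (Beta(1, K-1) for disjoint segments), which the tests
verify by Monte Carlo.

*Wavelet coherence* follows the Torrence-Compo construction: Morlet
omega0 = 6, scales s_j = s0 * 2^(j/12) with s0 = 2 dt up to the largest
period <= 12.8 s (Fourier period = 1.033 x scale; the angular-frequency
grid counts the Nyquist bin positive, which matters at the smallest
scales). The squared coherence

    R2 = |S(W_xy / s)|^2 / (S(|W_x|^2 / s) S(|W_y|^2 / s))

uses a smoothing operator S that is Gaussian in time (width = scale) and a
boxcar over 0.6/dj scale steps (the Morlet decorrelation length),
edge-renormalised. Without S the expression is identically 1 for any pair
— asserted in the tests as the reason S is mandatory. Cone-of-influence
points are retained in band averages by default (the 200->80 cropping
already removes the worst edge effects); a flag excludes them.

The production path computes channel CWTs once per epoch and forms the
861 pair maps in chunks, restricting the scale grid to the analysis band
plus the scale-smoothing half-width (band-interior values are identical to
a full-grid computation; tested). A single-precision mode (default in the
pipeline) agrees with the double-precision reference to ~1e-6 on band
averages, far below any decision boundary the classifier sees.

## ROI reduction

Oxygenation features are averaged over the 7 member channels of each ROI
(42 -> 6 values). Connectivity values are averaged over all channel pairs
connecting each unordered ROI pair, keeping within-ROI terms
(861 -> C(6,2) + 6 = 21 values). Between-ROI terms come first in canonical
ROI order, then within-ROI terms, so feature indices are stable.

## Classification

Features are z-scored per dimension with parameters fit on the training
fold only (a global variant exists behind `global_zscore` for fidelity
comparisons; it is leakage-prone and off by default). The classifier is a
two-class LDA whose pooled within-class covariance is shrunk toward a
scaled identity, C(g) = (1-g) S + g (tr S / p) I, with g the analytic
Ledoit-Wolf estimate (clipped to [1e-6, 1] so C is always positive
definite) or a fixed override. Priors are equal (the design is balanced);
a discriminant score of exactly 0 goes to the first class in canonical
label order.

Cross-validation holds out one landing per condition — all 4 x 4 = 16
combinations — training on 72 and testing on 24 epochs per fold; fold
accuracies are averaged per subject, then across subjects for the report.
Single features (12) and unordered feature pairs (66, column-wise
concatenation before normalization) are evaluated per chromophore.

Decoding significance uses the exact binomial chance level: the smallest
integer k with BinomCDF(k; n, 1/c) >= 1 - alpha, reported as 100 k / n
percent — 58.33% for n = 96, c = 2, alpha = 0.05, approaching 100/c as n
grows. The tail is computed exactly (no normal approximation).

## Problem sizes for the shipped studies

The test suite and `scripts/acceptance.py` run the following sizes, chosen
to complete on a single desktop CPU while leaving comfortable Monte-Carlo
margins:

- contrast and null classification studies: 5 simulated subjects, default
  42-channel montage, HbO chromophore, single features;
- coupling-recovery grid: 2-ROI montage (2 channels each), 3 coupling
  levels (0.1 / 0.5 / 0.9), 24 landings per level;
- accuracy-vs-contrast grid: same montage, manual coupling 0.25 / 0.5 /
  0.85 against auto 0.25, 4 subjects per level;
- estimator oracle checks: explicit-sum / DFT-matrix re-implementations on
  random 64-200-sample signals.

## Known limitations and open choices

- The literature the analysis derives from does not specify its Welch
  estimator, wavelet scale grid, or z-scoring scope; the defaults above
  are declared, configurable, and recorded in the run report rather than
  presumed canonical.
- The epoching sentence of the original design is ambiguous ("overlapping
  by 60 samples" vs. non-overlapping 10 s windows); onsets 60 samples
  apart are the only reading that fits 12 epochs into a 152 +/- 22 s
  landing (11 x 60 + 200 = 860 samples ~ 110 s), and the kept windows then
  overlap by 20 samples. The step is a parameter.
- Generator spectra are plausible rather than fitted to real recordings;
  LFO-band dominance and coupling monotonicity are asserted by tests, but
  absolute coherence or accuracy levels on real data are out of reach of
  any synthetic study.
- SNIRF support covers the continuous-wave amplitude subset this package
  writes (one /nirs element per landing, condition as the landing's
  stimulus); `validate_snirf` is an internal structural checker for that
  subset, not a full-spec validator.
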