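# Methods

This note documents the models, conventions and calibration behind
`restdecode`: what each stage computes, which choices were genuinely
open, and what the synthetic experiments do and do not establish.

## Spectral features

**Detrending.** The least-squares straight line (slope and intercept,
hence also the mean) is removed from every series before spectral
analysis. The operation is idempotent. Note that the removed line has
its own spectrum, concentrated in the lowest frequency bins; on
noise-free band-limited input a fraction of order 1% of total power can
appear below 0.01 Hz after detrending. This is a property of line
removal, not of the generator.

**Amplitude spectrum.** One-sided FFT spectrum with amplitude
`sqrt(2/N)·|rfft|` at every bin — the square root of power, uniformly
scaled. With this convention Parseval's identity (sum of squared
amplitudes = time-domain sum of squares) holds up to an O(1/N) boundary
term contributed by the DC and Nyquist bins; it is exact for signals
with no DC/Nyquist content. fALFF, a ratio, is independent of the
common scale. No taper is applied before the FFT by default; a Hann
window is available (`window="hann"`) but off, favouring fidelity to
the conventional processing chain over spectral hygiene.

**Band conventions.** The low band is half-open, `0.01 ≤ f < 0.08` Hz;
the full band is `0 < f ≤ 1/(2·TR)` (for TR = 2 s: 0–0.25 Hz with DC
excluded). Excluding DC makes fALFF's [0, 1] bound exact for detrended
series and is numerically inert (the DC bin of a detrended series is
zero). For N = 230 kept volumes at TR = 2 s this yields 32 in-band bins
of 115 non-DC bins, so white noise has expected fALFF ≈ 32/115 ≈ 0.278
(the Monte-Carlo mean is reproduced within three standard errors at
10,000 draws; the exact expectation differs from the bin fraction by a
few 10⁻⁴ because the Nyquist bin's amplitude has a slightly smaller
expectation than interior bins').

**Aggregation.** Numerator and denominator sum bin amplitudes (the
original fractional-amplitude definition, giving a fraction in [0, 1]).
A ratio-of-means variant (`aggregate="mean"`) is available; it rescales
the statistic by the bin-count ratio and is **not** bounded by 1.

**Degenerate input.** An identically-zero (post-detrend) series has no
defined fALFF and is reported as NaN with a warning — never as 0/0 or
silently as 0.

**Normalization.** Each recording's ROI (or voxel) map is divided by
its global mean over the analysis mask, making the masked mean exactly
1. In volumetric mode the order is: voxelwise fALFF → Gaussian smooth
(FWHM 6 mm, σ = FWHM/(2√(2 ln 2)) per axis) → global-mean divide, and
the default normalization mask is all voxels with positive, finite
fALFF (a whole-brain mask can be supplied instead — the choice is
configurable because either reading of "global mean" is defensible).
ROI spheres default to 5 mm radius (no radius is canonical for this
template; configurable).

## Feature selection

Per ROI, the n = 24 per-subject EC−EO differences enter a **paired**
Wilcoxon signed-rank test. The test is implemented as paired
(within-subject) even though such analyses are sometimes loosely
described as two-sample: only the paired reading produces a per-ROI Z
from 24 paired observations. Conventions: exact-zero differences are
dropped before ranking (classical reduced-sample treatment), midranks
for tied magnitudes, tie-corrected variance, no continuity correction,
sign positive when EC exceeds EO. Fewer than 5 non-zero pairs is an
error (the normal approximation is meaningless there); the all-zero
column returns Z = 0 with a degenerate flag.

Accuracy of the normal approximation was checked against exact
enumeration of all 2ⁿ sign patterns: with the half-unit continuity
correction the two-sided normal tail is within 0.03 of the exact p for
7 ≤ n ≤ 12 over the whole |Z| ≤ 2.5 range, and the uncorrected Z used
for selection is within 0.03 of the exact tail wherever |Z| ≥ 1.5 —
the region where the 1.96/2.25 thresholds act. Near the centre of the
discrete W⁺ lattice the uncorrected two-sided p undershoots the exact
one (by >0.1 at n = 5); this is irrelevant to threshold decisions and
is why the package's Z is only interpreted at its tails. At the study
size n = 24 the exact two-sided rate beyond |Z| > 1.96 is 4.91%.

The four selection criteria use strict inequalities exactly as
stated: |Z| > 1.96, Z > 1.96, Z > 2.25, Z < −1.96. Patterns are
ordered by descending |Z| with ties broken by template order, so
feature vectors are deterministic. No multiple-testing correction is
applied by default (matching the modelled procedure); Benjamini–
Hochberg screening is available as an opt-in (`fdr_alpha`).

## Decoding

Samples are labelled EC = +1, EO = −1. The default split halves each
condition's samples independently at random — the modelled scheme —
which can place one subject's EC recording in training and their EO
recording in testing; because both recordings share subject-level
signal, this leaks identity across the split. A subject-stratified
split (`by_subject=True`) is provided as the remedy. The classifier is
a soft-margin linear SVM at C = 1 (the toolbox default of the library
the modelled analysis names; configurable), no feature standardization
by default (none is described; z-scoring available). Decision values
exactly 0 predict EC, making predictions deterministic. ROC points are
swept over decision-value thresholds; AUC is the trapezoidal integral
and equals the Mann–Whitney statistic of the decision values.

**Circularity and the audit mode.** The modelled analysis computes Z
scores from *all* subjects before splitting, so the test half
participates in feature selection. On null cohorts (no condition
effect) this inflates held-out accuracy from 50% to roughly 75% —
measured, not hypothetical. `run_criterion_comparison(nested=True)` is
the audit mode: it draws a subject-stratified split first and performs
selection inside the training half only, restoring chance-level null
accuracy (≈50%). Accuracies from the default (replication) mode should
therefore be read as descriptive of the procedure, not as unbiased
generalization estimates.

## Synthetic cohorts

Each ROI's series is

    baseline + amp · Σₖ sin(2π fₖ t + φₖ) + pink(t) + white(t)

with K = 5 unit-amplitude sinusoids, frequencies drawn per recording
from the DFT bins of the trimmed series inside [0.01, 0.08) Hz
(`snap_to_bins=True`; snapping keeps all noise-free power inside the
band — an off-bin tone near the band edge would leak a few percent
through rectangular-window sidelobes — and an off-grid mode exists for
leakage studies), i.i.d. phases, pink noise with amplitude shaped as
f^(−β/2) (β = 1) scaled to unit SD, and white noise with σ = 2. The
per-subject factor `amp` is lognormal (σ = 0.2) and shared between a
subject's two recordings, so the paired design is genuinely easier
than independent groups; frequencies, phases and noise are drawn
independently per recording (two separate scans). In the eyes-closed
condition the oscillation amplitude of the effect ROIs (default: the
first 10 sensorimotor template regions) is multiplied by
1 + effect_size, with effect_size = 1 by default — the direction
matching the dominant finding (EC > EO in sensorimotor regions).

Acquisition geometry follows the modelled study: 24 subjects × 2
conditions, TR = 2 s, 240 volumes of which the *pipeline* (not the
generator) discards the first 10. Generation is a pure function of
(config, seed): identical configs reproduce cohorts bit for bit.

**Calibration.** noise_sigma was calibrated by Monte-Carlo so that the
planted effect is reliably detectable and then frozen: at σ = 2, all
10 effect ROIs exceed |Z| > 1.96 in ≥ 90% of replicates (in practice
10/10 in every replicate observed), the null selection rate matches
the exact 4.91%, and audit-mode null accuracy is statistically
indistinguishable from 50%. No magnitudes were available to match for
real data, so these are simulation-design choices, not empirical fits.

**An instructive side effect.** Because features are divided by the
recording's global mean, a positive amplitude effect in 10 ROIs
*lowers* the normalized fALFF of the other 150 ROIs under EC. Null
ROIs therefore populate the Z < −1.96 pattern, which decodes above
chance (≈85% at the default effect size) yet clearly below the
positive patterns (100%) — reproducing the qualitative criterion
ordering reported for real data, where the negative pattern was also
the weakest. Global-mean normalization couples ROIs; "null" is only
exact at effect_size = 0.

**What the generator does not emulate.** Hemodynamic dynamics, motion
and physiological artifacts, spatial autocorrelation between ROIs
(ROI-level mode draws noise independently per ROI), session/order
effects, and realistic inter-subject spatial variability. Passing
synthetic tests therefore validates the statistical machinery and its
calibration — not preprocessing robustness on real scanner data, nor
the real-data accuracy figures, which require the original (undeposited)
cohort.

## Problem sizes used in tests

Desk checks run on the built-in 28-region table. Monte-Carlo suites
use 100 study-sized cohorts (24 subjects, 160 ROIs, 240 volumes) for
the null and effect experiments, 10,000 draws for the white-noise
fALFF expectation, and full 2ⁿ enumeration up to n = 12 for the
signed-rank oracle; unit tests use smaller cohorts (6–12 subjects)
where the property under test does not depend on the study size.
Volumetric-mode tests run on a 3-ROI template in a small 3 mm grid and
a 6-subject end-to-end run on the 28-region template.

## Known limitations

- The normal-approximation Z is reported even at n = 24 where the
  exact distribution is computable; this mirrors the modelled
  procedure. The exact-enumeration oracle in the test suite bounds the
  resulting error at the thresholds.
- The published Z table the fixture reproduces contains two rows whose
  coordinates duplicate earlier rows under different names, and its Z
  values repeat in blocks that a continuous paired statistic at n = 24
  would not naturally produce; the fixture reproduces the table
  verbatim (flagged), and no attempt is made to regenerate those exact
  values from simulation.
- Accuracies from the replication-mode pipeline are optimistic by
  construction (see the audit mode above).
- Volumetric mode paints ROI-level signal into spheres; it exercises
  the imaging path (NIfTI I/O, smoothing, sphere aggregation) but is
  not a realistic voxel-level simulation.
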