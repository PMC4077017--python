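# Methods

This note documents the statistical model behind `eegfmri`, the choices made
where the design was open, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## The reliability statistic and its calibration

For each IC and each post-stimulus time point the package computes a Welch
two-sample *t* between correct-Nogo and correct-Go epochs (or a one-sample
*t* against zero for the visual path, on pooled correct epochs; epochs are
baseline-corrected on the 200 ms pre-stimulus interval, so "zero" is the
baseline).  The *t* value is standardized to

    Z = t / sqrt(n_ref),

where `n_ref` is the epoch count of the smaller condition; the degrees of
freedom are recorded conservatively as `n_ref − 1`.  *Z* is a per-trial
signal-to-noise ratio: it measures the size of the condition difference per
single trial rather than per average.  The fixed threshold |Z| > 0.275 is
anchored to the design: with 300 trials per run, ~90 are Nogo, and a
two-sample *t* at two-sided p = 0.01 with df = 89 is ≈ 2.61 =
0.275 · √90.  The acceptance suite recomputes this inversion
(2·P(T₈₉ > 0.275·√90) = 0.0107 → 0.01 at two decimals).

Only correct trials enter the classification; omissions and commissions are
kept as separate event types and contribute only to the Errors onset
regressor and to the amplitude vectors (which cover *all* trials, because
the EEG regressor must span the whole run).

## Latency ranges, polarity and containment

Maximal contiguous runs of |Z| above threshold are reported as half-open
intervals `[t_on, t_off)` on the 100 Hz sample grid (no sub-sample
interpolation; `t_on` is the first above-threshold sample, `t_off` the first
below-threshold sample after the run).  Each range's polarity is the sign of
the condition average with the larger mean |amplitude| over the range;
Go-dominant ranges are discarded (ties count as Nogo-dominant).  A range is
assigned to an analysis window only if it both rises above threshold after
the window start and falls below before the window end; a range inside the
early/late overlap is assigned to both.  Windows: early = [200 ms, median
correct-Go RT], late = [RT − 100 ms, RT + 300 ms], visual = [90, 140] ms.
There is no minimum-duration filter beyond containment; a single
above-threshold sample is a valid range.

## IC scale convention

A square unmixing matrix leaves the split of scale between an IC's
activation and its mixing column arbitrary.  `fit_unmixing` (PCA whitening +
extended infomax, fitted per run on the continuous cleaned data) normalizes
mixing columns to unit norm, so activations carry the component's
channel-space magnitude in µV-equivalent units.  This matters when amplitude
vectors of several selected ICs are summed into one regressor: in
whitened unit-variance units every IC — including pure-noise ICs whose
ranges pass the threshold — would contribute equally, diluting the summed
regressor; in the unit-column convention, components that actually carry
signal dominate the sum.  On synthetic runs this convention raised the
median recovery correlation of planted trial amplitudes from ~0.76 to ~0.85.

## Artifact-IC flagging

Heartbeats and blinks are detected on the ECG/EOG channel: provisional peaks
on the bandpassed trace, a time-domain template averaged around them, then
matched-filter peaks above 0.6 of the maximum with a refractory period
(0.4 s cardiac, 0.25 s blink).  An IC is flagged as artifactual when the RMS
of its event-locked average exceeds (a) the 99th percentile of the same
statistic over 200 circularly shifted surrogate event sets *and* (b) twice
the surrogate median.  The percentile alone is a pure significance test and
is correctly calibrated (~1% false flags on independent noise), but with a
square decomposition nearly every IC carries a trace of the large BCG
artifact, and a significance-only rule flags most of the decomposition,
including task components.  The 2× effect-size floor restricts flags to ICs
on which the artifact genuinely loads; planted task sources survive flagging
in every tested seed.  Flagged ICs are excluded from all candidate lists
downstream.

## Regressor construction and GLM

The per-trial amplitude vector (one value per stimulus, 1 Hz) is fit with a
cubic smoothing spline (`scipy.interpolate.make_smoothing_spline`, GCV
smoothing by default; the smoothing parameter is exposed) and evaluated at
volume acquisition times `k · TR` (volume onsets; no slice-timing offset),
clamped to boundary values outside the trial span.  The resampled series is
median-centered and scaled to unit inter-quartile range, convolved with the
canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1:6, 32 s,
sampled 16× oversampled then decimated to the scan grid), and orthogonalized
against the HRF-convolved Go/Nogo/Errors onset regressors plus intercept
(least squares; by Frisch–Waugh the onset betas of the subsequent GLM are
unchanged by including the orthogonalized column — asserted numerically).
The visual regressor is not orthogonalized.  Median-centering before
convolution is harmless under a GLM with intercept and tames edge effects.

The first-level design adds a discrete-cosine high-pass set (periods above
128 s; `floor(2·n·TR/128)` columns — 5 for a 152-volume run) and an
intercept, and is fit by per-voxel OLS; the EEG column's beta/t/Z images are
the contrast.  The two runs' beta images are averaged per subject; group
maps are voxelwise one-sample or paired *t*; clusters are formed from
one-sided supra-threshold voxels (p < 0.005 by default) under
26-connectivity and removed below 20 voxels.  High-pass-as-regressors keeps
OLS exact; no prewhitening is applied, so first-level *p* values are
approximate under serially correlated noise, while group-level inference
(across independent subjects) remains exactly calibrated — the null-cohort
calibration in the acceptance suite is therefore evaluated at the group
level, where the measured supra-threshold fraction matches 0.005 within
Monte-Carlo error.

## The synthetic generator

`gen_paradigm` realizes the constrained stimulus sequence as a two-state
Markov chain: P(Nogo | previous Go) = p/(1−p) with stationary start, giving
a long-run Nogo fraction of exactly p = 0.29 while forbidding Nogo→Nogo.
Go RTs are log-normal (median 0.40 s, the middle of the observed per-subject
range; shape 0.20); commission/omission rates default to 10%/2%.

`gen_eeg` mixes, at 100 Hz into 64 channels (62 scalp + EOG + ECG):

- an **inhibition source**: Hann bump confined to 250–350 ms post-stimulus,
  per-trial log-normal amplitude (shape 0.5), full on Nogo, 20% leakage on
  Go (so the Nogo−Go contrast, not mere stimulus response, is the selective
  signal);
- a **visual source**: bump at 90–140 ms on every stimulus, own amplitudes;
- **BCG**: quasi-periodic (1.1 ± 0.06 s) biphasic waveform plus matching
  QRS-like ECG-channel deflections;
- **blinks**: random (~0.2 Hz, 1 s refractory) bumps with matching
  EOG-channel deflections;
- optionally a **gradient artifact**: a fixed high-amplitude waveform
  repeated exactly every TR, locked to scan triggers;
- background noise: band-limited 1/f² Gaussian noise (10 µV RMS per scalp
  channel) plus a 0.1 µV broadband amplifier floor.

Source topographies are smooth random unit-norm vectors over the scalp
channels, rejection-sampled to pairwise |cos| ≤ 0.5 — physically distinct
generators have distinct scalp patterns, and near-collinear draws (an
artifact of low channel counts) would make any linear unmixing fuse sources.
Evoked gains default to 60/40 µV at unit topography norm, i.e. ~10 µV at the
strongest channel — the upper end of realistic single-trial evoked
magnitudes against a 10 µV background.

The noise spectrum deserves a note.  The containment rule's specificity
depends on the *temporal smoothness* of the across-trial t-process: by
Rice's formula the rate of threshold crossings scales with the noise
spectrum's second moment, so a broadband background produces many brief
above-threshold excursions that trivially fit inside a 200 ms window, while
a drift-dominated background produces long excursions that violate strict
containment.  In-scanner EEG after gradient correction is dominated by
low-frequency residuals, which is the regime modeled here (1/f²).  Even so,
with ~10 retained candidate ICs the measured probability that a
no-source run yields at least one false early-window selection is ~25% —
the strict containment and Nogo-dominance rules remove most but not all
false candidates.  The practical consequence, matching the method's
real-data behavior, is that summed regressors can include a few
noise-dominated ranges; the unit-column scale convention (above) keeps their
influence small.

`gen_bold` plants a ~32-voxel spherical coupled region in a 10³ grid:
active voxels get HRF-convolved condition effects (Go 0.5, Nogo 1.0, in
percent-signal-change units of a 100-unit baseline; the HRF kernel is
normalized to unit peak so "effect 1" means a 1% peak response per isolated
event) plus `coupling_beta ×` the median-centered per-trial inhibition
amplitude, sampled at acquisition times, with AR(1) (φ = 0.3, σ = 0.5)
noise everywhere.

What the generator does **not** emulate: no dipole-forward head model
(topographies are random smooth vectors), no raw 5 kHz gradient-locked
acquisition (synthesis is at the working rate; the gradient artifact option
exists for testing the template subtraction), no spatial autocorrelation or
motion in BOLD, no slice timing.  Passing recovery tests therefore show the
*procedure* is correct and well-calibrated under its own assumptions — not
that it would meet the same numbers on real recordings.

## Problem sizes used in tests

The test and acceptance computations keep the trial structure that anchors
the Z calibration (300 trials, 29% Nogo) but scale hardware dimensions:
selection/recovery runs use 16 channels and 141 volumes; the square-ICA
check uses the full 64 channels on a 120 s run; group recovery uses 8
subjects × 2 runs on the 10³ voxel grid with the regressor built from the
planted amplitude vectors.  These sizes were chosen so the whole suite
completes in minutes on one CPU while every statistical claim is tested at
its calibrated trial counts.

## Known limitations

- The exact t→Z standardization is a reconstruction calibrated to the
  0.275 ↔ p = 0.01 (df = 89) anchor; other standardizations (e.g.
  pooled-variance effect sizes) would change selected ranges slightly.
- Whether a range inside the early/late overlap should feed both regressors
  is an open choice; both tags are assigned (a config switch can restrict
  selection to one window).
- No multiple-comparison control across ICs/time points at the selection
  stage, by design; specificity rests on the threshold, dominance and
  containment rules, with the measured false-selection behavior above.
- First-level OLS without prewhitening; FWE/small-volume correction and
  spatial normalization are out of scope (cluster tables report uncorrected
  voxel p and extent only).
- The N2 regressor keeps its raw (negative-going) sign by default; an
  `invert` flag is provided.
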