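# eegfmri

Data-driven selection of task-related EEG independent components and
single-trial coupling of their amplitude variability to fMRI BOLD, for
simultaneous EEG/fMRI experiments — here a visual Go/Nogo response-inhibition
paradigm.

## The problem and the method

In simultaneous EEG/fMRI, trial-to-trial variability of an evoked EEG
component can be used as a predictor of the BOLD signal
("integration by prediction").  The hard part is choosing *which* EEG signal
to extract per participant without hand-picking components or assuming a
fixed ERP template.  This package implements an automated procedure:

1. **Preprocess** the in-scanner EEG: gradient-artifact template subtraction
   (sliding average over 21 volume epochs), 0.2–48 Hz zero-phase bandpass,
   downsample to 100 Hz.
2. **Decompose** each run with square extended-infomax ICA (64 channels →
   64 ICs); detect heartbeats/blinks on the ECG/EOG channels by template
   matching and flag BCG/blink ICs with an event-locked surrogate test.
3. **Classify** ICs by pointwise reliability: epoch IC activations
   (−200…1000 ms, 200 ms baseline), compute pointwise Welch *t* between
   correct Nogo and Go epochs, and standardize to a per-trial
   signal-to-noise score

   *Z* = *t* / √*n*<sub>ref</sub>,  *n*<sub>ref</sub> = epochs in the
   smaller condition.

   The fixed threshold |*Z*| > 0.275 corresponds to a two-sided *p* = 0.01
   (two-sample *t*, df = 89 — the ~90 Nogo trials of a 300-trial run).
4. **Select** maximal contiguous |*Z*| > 0.275 latency ranges that are
   Nogo-dominant and *wholly contained* in an analysis window:
   **early** = [200 ms, median correct-Go RT],
   **late** = [RT − 100 ms, RT + 300 ms] (or **visual** = [90, 140] ms with a
   one-sample test against baseline).
5. **Extract** per-trial mean amplitudes over each selected range,
   polarity-corrected so the Nogo-dominant deflection is positive, summed
   across ranges per window; plus a classical N2 (280–340 ms) / P3
   (350–570 ms) path at Cz re-referenced to TP9/TP10.
6. **Regress**: cubic-smoothing-spline resample the amplitude vector
   (1 Hz trials) to acquisition times (TR = 2.25 s), normalize to unit IQR,
   convolve with the canonical double-gamma HRF, orthogonalize to the
   Go/Nogo/Errors onset regressors.
7. **GLM**: voxelwise OLS with a 128 s discrete-cosine high-pass, run-wise
   contrast images averaged per subject, group one-sample/paired *t*, and
   cluster-extent thresholding (*p* < 0.005 unc., *k* = 20, 26-connectivity).

Because no public dataset exists for this design, the package ships a
first-class synthetic generator (`eegfmri.synth`) that emulates the paradigm
(300 stimuli/run, 29% Nogo with every Nogo followed by a Go, 1 s SOA, two
runs, TR 2.25 s, 157 volumes, 5 discarded) and plants a ground-truth
inhibition source, visual source, BCG/blink/gradient artifacts, and
amplitude-coupled BOLD — so every stage is testable against known truth.

## Worked example

Simulate a synthetic subject, preprocess run 0, and select Nogo-related ICs:

```bash
eegfmri simulate --out demo --seed 3
# wrote 2 runs to demo

eegfmri preprocess --eeg demo/sub-00_run-0_eeg.h5 --out demo/run0.h5 \
    --skip-gradient --seed 3
# 64 ICs, flagged [0, 1, 2, 9, 10, 17, 37, 41, 42, 46, 59]

eegfmri select --run demo/run0.h5 --events demo/sub-00_run-0_events.tsv \
    --out demo/sel.json
# 20 selected ranges -> demo/sel.json
```

The first entries of `demo/sel.json`:

```json
{"ic": 8,  "t_on": 0.27, "t_off": 0.33, "polarity": -1, "windows": ["early"]},
{"ic": 12, "t_on": 0.25, "t_off": 0.35, "polarity": 1,  "windows": ["early"]}
```

Read: ICs 8 and 12 showed reliably larger (|Z| > 0.275) Nogo amplitude in a
latency range contained in the early window; the planted inhibition source is
active at 250–350 ms, and IC 12 recovers exactly that range.  The polarity is
the sign of the Nogo average over the range; amplitudes extracted with
polarity −1 are flipped so that a stronger inhibition response is always a
more positive regressor value.  `eegfmri run` chains everything
(simulate → … → group cluster tables) into a `report.json`.

The same steps work on real data: `read_recording()` accepts BrainVision
(.vhdr) and EDF files, events are BIDS-style TSV, BOLD is NIfTI-1.

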