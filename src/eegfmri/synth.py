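"""Synthetic simultaneous EEG/fMRI generator with planted ground truth.

Emulates a visual Go/Nogo paradigm inside the scanner: 300 stimuli per run at
a 1 s stimulus-onset asynchrony (500 ms letter + 500 ms blank), ~29% Nogo
with every Nogo followed by at least one Go, two runs per subject,
TR = 2.25 s with 157 volumes of which the first 5 are equilibration discards.

The EEG signal model realizes exactly the structure the selection method
assumes: an inhibition-related source emitting a smooth bump in a fixed
post-stimulus latency interval with per-trial log-normal amplitude (full
amplitude on Nogo trials, a leakage fraction on Go trials), a visual source
active 90-140 ms on every stimulus, plus ballistocardiogram, blink and
(optionally) gradient artifacts.  BOLD in a planted voxel mask is coupled to
the median-centered per-trial inhibition amplitudes through a canonical HRF.

Everything planted is recorded in :class:`GroundTruth` so downstream stages
can be scored against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import EventTable, Recording, VolumeSeries, EOG, ECG, SCALP

logger = logging.getLogger("eegfmri")


class SimConfigError(ValueError):
    """A simulation parameter is infeasible or inconsistent."""


@dataclass
class SimConfig:
    """Study conditions of the synthetic paradigm.  Defaults are the
    conditions of the emulated experiment; ``seed`` is mandatory."""

    seed: int
    n_trials: int = 300
    p_nogo: float = 0.29
    soa_s: float = 1.0
    rt_median_s: float = 0.40          # inside the observed 0.32-0.49 s range
    rt_sigma: float = 0.20             # log-normal shape of Go RTs
    p_commission: float = 0.10         # press on Nogo
    p_omission: float = 0.02           # no press on Go
    n_channels: int = 64               # 62 scalp + EOG + ECG
    sfreq: float = 100.0
    tr_s: float = 2.25
    n_volumes: int = 157
    n_discard: int = 5
    # EEG signal model
    inhibition_window: tuple = (0.25, 0.35)
    inhibition_gain: float = 60.0      # uV at unit trial amplitude, unit topography
    go_leak: float = 0.2               # Go-trial fraction of the inhibition amplitude
    visual_window: tuple = (0.09, 0.14)
    visual_gain: float = 40.0
    amp_sigma: float = 0.5             # log-normal shape of trial amplitudes
    noise_sigma: float = 10.0          # low-frequency background, uV RMS per channel
    noise_exponent: float = 2.0        # spectral slope: power ~ 1/f^exponent
    white_sigma: float = 0.1           # amplifier noise floor, uV
    bcg_gain: float = 80.0
    bcg_period_s: float = 1.1
    bcg_jitter_s: float = 0.06
    blink_gain: float = 40.0
    blink_rate_hz: float = 0.2
    gradient: bool = False
    gradient_gain: float = 2000.0
    # BOLD signal model
    vol_shape: tuple = (10, 10, 10)
    active_radius_vox: float = 2.0     # ~33-voxel spherical coupled region
    coupling_beta: float = 0.5
    go_effect: float = 0.5
    nogo_effect: float = 1.0
    bold_baseline: float = 100.0
    bold_sigma: float = 0.5
    bold_ar1: float = 0.3

    def __post_init__(self):
        if self.seed is None:
            raise SimConfigError("seed is mandatory")
        if not 0 <= self.p_nogo <= 0.5:
            raise SimConfigError(
                "p_nogo must lie in [0, 0.5]: every Nogo must be followed by a Go"
            )
        if self.n_trials < 1 or self.soa_s <= 0 or self.sfreq <= 0:
            raise SimConfigError("n_trials, soa_s, sfreq must be positive")
        for name in ("inhibition_window", "visual_window"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi <= 1.0:
                raise SimConfigError(f"{name} must lie inside the (0, 1] s epoch span")

    def run_config(self, run_index):
        """Per-run configuration with a seed derived by a fixed offset."""
        return replace(self, seed=(self.seed * 1000 + 7919 * run_index) % (2**31 - 1))


@dataclass
class GroundTruth:
    """Everything planted into one synthetic run."""

    source_topographies: dict            # name -> (n_channels,) unit-norm column
    trial_amplitudes: dict               # name -> (n_trials,) gains, >= 0
    source_timecourses: dict             # name -> continuous task-source trace
    source_gains: dict                   # name -> mixing gain (uV)
    artifact_sources: dict               # name -> continuous time course
    artifact_times: dict                 # name -> event times (s)
    active_voxel_mask: np.ndarray = None
    coupling_betas: np.ndarray = None
    seed: int = None


# ---------------------------------------------------------------------------
# Paradigm
# ---------------------------------------------------------------------------

def gen_paradigm(config):
    """Generate one run's event table.

    Nogo trials occur at a long-run rate of ``p_nogo`` under the constraint
    that a Nogo is never followed by another Nogo.  This is realized as a
    two-state Markov chain with P(Nogo | previous Go) = p/(1-p), whose
    stationary Nogo fraction is exactly p; the first trial is drawn from the
    stationary distribution.
    """
    rng = np.random.default_rng(config.seed)
    p = config.p_nogo
    q = p / (1.0 - p) if p < 1 else 1.0  # conditional rate after a Go
    types = []
    prev_nogo = rng.random() < p  # stationary start
    types.append("Nogo" if prev_nogo else "Go")
    for _ in range(1, config.n_trials):
        is_nogo = (not prev_nogo) and (rng.random() < q)
        types.append("Nogo" if is_nogo else "Go")
        prev_nogo = is_nogo

    onsets = np.arange(config.n_trials) * config.soa_s
    mu = np.log(config.rt_median_s)
    rows = []
    for onset, ttype in zip(onsets, types):
        if ttype == "Go":
            pressed = rng.random() >= config.p_omission
        else:
            pressed = rng.random() < config.p_commission
        rt = float(np.exp(rng.normal(mu, config.rt_sigma))) if pressed else np.nan
        response = (
            ("correct" if pressed else "omission")
            if ttype == "Go"
            else ("commission" if pressed else "correct")
        )
        rows.append((onset, 0.5, ttype, rt, response))
    df = pd.DataFrame(
        rows, columns=["onset", "duration", "trial_type", "response_time", "response"]
    )
    return EventTable(df)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _smooth_unit_topography(rng, n_scalp, n_channels):
    """Random spatially smooth unit-norm mixing column over scalp channels."""
    from scipy.ndimage import gaussian_filter1d

    v = gaussian_filter1d(rng.standard_normal(n_scalp), sigma=2.0,
                          mode="nearest")
    col = np.zeros(n_channels)
    col[:n_scalp] = v / np.linalg.norm(v)
    return col


def _bump(n):
    """Unit-peak smooth unimodal bump (Hann window) of n samples."""
    return np.hanning(n + 2)[1:-1]


def _colored_noise(rng, shape, sfreq, sigma, exponent=1.0, f_floor=0.2):
    """Band-limited 1/f^exponent Gaussian noise, RMS ``sigma`` per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    gain = 1.0 / np.maximum(freqs, f_floor) ** (exponent / 2.0)
    gain[0] = 0.0
    spec = np.fft.rfft(white, axis=-1) * gain
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    return sigma * x / np.maximum(rms, 1e-30)


def gen_eeg(events, config):
    """Mix planted sources and artifacts into a continuous Recording.

    Returns ``(recording, ground_truth)``.  The recording's clock equals the
    run clock (t = 0 at the first analyzed volume; stimulus onsets are the
    event-table onsets).  Scan triggers carry code ``"scan"``; stimulus
    triggers carry the trial type.
    """
    rng = np.random.default_rng(config.seed + 1)
    sf = config.sfreq
    n_ch = config.n_channels
    if n_ch < 6:
        raise SimConfigError("need at least 6 channels (>= n_sources + aux)")
    n_scalp = n_ch - 2
    n_scans = config.n_volumes - config.n_discard
    duration = max(n_scans * config.tr_s, events.onsets[-1] + 1.5)
    n_samples = int(round(duration * sf))
    t = np.arange(n_samples) / sf
    onsets = events.onsets
    n_trials = len(events)
    is_nogo = (events.table["trial_type"] == "Nogo").to_numpy()

    def lognorm_amps(n):
        return np.exp(rng.normal(0.0, config.amp_sigma, size=n))

    # --- task sources -----------------------------------------------------
    amps_inh = lognorm_amps(n_trials)
    amps_vis = lognorm_amps(n_trials)
    src_inh = np.zeros(n_samples)
    src_vis = np.zeros(n_samples)
    for win, src, amps, leak in (
        (config.inhibition_window, src_inh, amps_inh, config.go_leak),
        (config.visual_window, src_vis, amps_vis, None),
    ):
        i0 = int(round(win[0] * sf))
        i1 = int(round(win[1] * sf))
        shape = _bump(i1 - i0)
        for k in range(n_trials):
            s = int(round(onsets[k] * sf)) + i0
            if s < 0 or s + len(shape) > n_samples:
                continue
            gain = 1.0 if leak is None or is_nogo[k] else leak
            src[s:s + len(shape)] += amps[k] * gain * shape

    # --- BCG --------------------------------------------------------------
    beat_times = []
    tt = 0.3
    while tt < duration - 0.5:
        beat_times.append(tt)
        tt += config.bcg_period_s + rng.normal(0.0, config.bcg_jitter_s)
    beat_times = np.asarray(beat_times)
    src_bcg = np.zeros(n_samples)
    bcg_shape = _bump(int(0.5 * sf)) * np.sin(np.linspace(0, 2 * np.pi, int(0.5 * sf)))
    ecg_trace = np.zeros(n_samples)
    qrs = np.exp(-0.5 * ((np.arange(-10, 11) / 2.0) ** 2))
    for bt in beat_times:
        s = int(round(bt * sf))
        if s + len(bcg_shape) <= n_samples:
            src_bcg[s:s + len(bcg_shape)] += bcg_shape
        e0 = s + int(0.05 * sf)
        if 0 <= e0 - 10 and e0 + 11 <= n_samples:
            ecg_trace[e0 - 10:e0 + 11] += 500.0 * qrs

    # --- blinks -----------------------------------------------------------
    blink_times = []
    tt = rng.exponential(1.0 / config.blink_rate_hz)
    while tt < duration - 0.5:
        blink_times.append(tt)
        tt += 1.0 + rng.exponential(1.0 / config.blink_rate_hz)
    blink_times = np.asarray(blink_times)
    src_blk = np.zeros(n_samples)
    blk_shape = _bump(int(0.4 * sf))
    for bt in blink_times:
        s = int(round(bt * sf))
        if s + len(blk_shape) <= n_samples:
            src_blk[s:s + len(blk_shape)] += blk_shape
    eog_trace = np.zeros(n_samples)
    for bt in blink_times:
        s = int(round(bt * sf))
        if s + len(blk_shape) <= n_samples:
            eog_trace[s:s + len(blk_shape)] += 200.0 * blk_shape

    # --- mixing -----------------------------------------------------------
    # physically distinct generators have distinct scalp patterns: redraw
    # until pairwise |cos| <= 0.5 so sources are not accidentally collinear
    topo = {}
    for name in ("inhibition", "visual", "bcg", "blink"):
        for _ in range(500):
            cand = _smooth_unit_topography(rng, n_scalp, n_ch)
            if all(abs(cand @ other) <= 0.5 for other in topo.values()):
                break
        topo[name] = cand
    gains = {
        "inhibition": config.inhibition_gain,
        "visual": config.visual_gain,
        "bcg": config.bcg_gain,
        "blink": config.blink_gain,
    }
    sources = {
        "inhibition": src_inh,
        "visual": src_vis,
        "bcg": src_bcg,
        "blink": src_blk,
    }
    data = np.zeros((n_ch, n_samples))
    for name in topo:
        data += np.outer(topo[name] * gains[name], sources[name])

    if config.noise_sigma > 0:
        data[:n_scalp] += _colored_noise(
            rng, (n_scalp, n_samples), sf, config.noise_sigma,
            exponent=config.noise_exponent,
        )
    if config.white_sigma > 0:
        data += config.white_sigma * rng.standard_normal((n_ch, n_samples))
    data[n_scalp] += eog_trace      # EOG channel
    data[n_scalp + 1] += ecg_trace  # ECG channel

    # --- triggers ---------------------------------------------------------
    triggers = []
    scan_step = int(round(config.tr_s * sf))
    for k in range(n_scans):
        s = k * scan_step
        if s < n_samples:
            triggers.append((s, "scan"))
    for onset, ttype in zip(onsets, events.table["trial_type"]):
        s = int(round(onset * sf))
        if 0 <= s < n_samples:
            triggers.append((s, str(ttype)))
    triggers.sort(key=lambda sc: sc[0])

    # --- optional gradient artifact (locked to scan triggers) -------------
    grad_trace = np.zeros(n_samples)
    if config.gradient:
        wave = rng.standard_normal(scan_step)
        weights = 0.5 + rng.random(n_ch)
        for k in range(n_scans):
            s = k * scan_step
            e = min(s + scan_step, n_samples)
            grad_trace[s:e] += wave[: e - s]
        data += config.gradient_gain * np.outer(weights, grad_trace)

    labels = [f"EEG{i + 1:03d}" for i in range(n_scalp)] + ["EOG", "ECG"]
    rec = Recording(
        data=data,
        sfreq=sf,
        channel_labels=labels,
        channel_kinds=[SCALP] * n_scalp + [EOG, ECG],
        triggers=triggers,
    )
    truth = GroundTruth(
        source_topographies=topo,
        trial_amplitudes={
            "inhibition": amps_inh * np.where(is_nogo, 1.0, config.go_leak),
            "visual": amps_vis,
        },
        source_timecourses={"inhibition": src_inh, "visual": src_vis,
                            "bcg": src_bcg, "blink": src_blk},
        source_gains=dict(gains),
        artifact_sources={"bcg": src_bcg, "blink": src_blk, "gradient": grad_trace},
        artifact_times={"bcg": beat_times, "blink": blink_times},
        seed=config.seed,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def active_mask(config):
    """Spherical coupled region in the center of the volume grid."""
    nx, ny, nz = config.vol_shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    c = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    return r2 <= config.active_radius_vox**2


def gen_bold(events, truth, config):
    """Simulate the BOLD series coupled to the planted trial amplitudes.

    Active voxels follow baseline + HRF * [condition effects + beta *
    (trial amplitude - median)] sampled at acquisition times, plus AR(1)
    noise; inactive voxels are baseline + noise.  Fills
    ``truth.active_voxel_mask`` and ``truth.coupling_betas``.
    """
    from nilearn.glm.first_level.hemodynamic_models import spm_hrf

    rng = np.random.default_rng(config.seed + 2)
    mask = active_mask(config)
    betas = np.where(mask, config.coupling_beta, 0.0)
    truth.active_voxel_mask = mask
    truth.coupling_betas = betas

    amps = np.asarray(truth.trial_amplitudes["inhibition"], dtype=float)
    if len(amps) != len(events):
        raise SimConfigError("trial_amplitudes not aligned with events")
    if np.any(betas[~mask] != 0):
        raise SimConfigError("coupling outside the active mask")
    amps_c = amps - np.median(amps)
    cond = events.condition()
    cond_eff = np.where(
        cond == "go_correct", config.go_effect,
        np.where(cond == "nogo_correct", config.nogo_effect, 0.0),
    )

    over = 16
    dt = config.tr_s / over
    # acquisition clock: volume j is acquired at (j - n_discard) * TR
    t0 = -config.n_discard * config.tr_s
    n_fine = int(np.ceil((config.n_volumes * config.tr_s) / dt)) + 1
    kernel = spm_hrf(config.tr_s, oversampling=over, time_length=32.0)
    kernel = kernel / kernel.max()  # unit peak: effects are in % signal change

    def fine_conv(weights):
        train = np.zeros(n_fine)
        idx = np.round((events.onsets - t0) / dt).astype(int)
        ok = (idx >= 0) & (idx < n_fine)
        np.add.at(train, idx[ok], weights[ok])
        return np.convolve(train, kernel)[:n_fine]

    vol_idx = np.round((np.arange(config.n_volumes) * config.tr_s) / dt).astype(int)
    resp_cond = fine_conv(cond_eff)[vol_idx]
    resp_amp = fine_conv(amps_c)[vol_idx]

    shape = tuple(config.vol_shape) + (config.n_volumes,)
    data = np.full(shape, config.bold_baseline, dtype=float)
    data[mask] += resp_cond + config.coupling_beta * resp_amp
    # condition effects are present wherever the task region is active
    if config.bold_sigma > 0:
        noise = rng.standard_normal(shape) * config.bold_sigma
        if config.bold_ar1 != 0:
            phi = config.bold_ar1
            for j in range(1, config.n_volumes):
                noise[..., j] += phi * noise[..., j - 1]
            noise *= np.sqrt(1 - phi**2)
        data += noise
    return VolumeSeries(data=data, tr_s=config.tr_s, n_discard=config.n_discard)


def gen_subject(config, n_runs=2):
    """Generate ``n_runs`` independent runs (events, recording, truth, bold)."""
    out = []
    for r in range(n_runs):
        cfg = config.run_config(r)
        ev = gen_paradigm(cfg)
        rec, truth = gen_eeg(ev, cfg)
        bold = gen_bold(ev, truth, cfg)
        out.append((ev, rec, truth, bold))
    return out
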