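"""Continuous-EEG cleaning and per-run ICA decomposition.

Order of operations: gradient-artifact template subtraction (sliding-average
template per volume epoch), zero-phase 0.2-48 Hz bandpass and downsampling to
100 Hz, then a square extended-infomax unmixing fit on the continuous data of
each run separately.  BCG and blink artifact ICs are identified by an
event-locked-average test against a circular-shift surrogate null and flagged
for exclusion; IC time courses themselves (minus flagged ICs) feed the
selection stage, while a back-projected channel-space cleanup is produced
only for the ERP comparison path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_formats import Recording

logger = logging.getLogger("eegfmri")


class TimingError(RuntimeError):
    """Scan triggers are not regularly spaced."""


class FitError(RuntimeError):
    """ICA failed to converge; carries diagnostics."""


class DetectionError(RuntimeError):
    """Too little structure in an auxiliary channel to detect events."""


class ConfigError(ValueError):
    pass


@dataclass
class Decomposition:
    """Square unmixing/mixing pair with artifact flags.

    ``unmixing @ data`` yields IC activations for any sample without
    repeating the fit; ``mixing`` is its (pseudo-)inverse.
    ``artifact_flags`` maps IC index -> reason ("bcg" or "blink").
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    artifact_flags: dict = field(default_factory=dict)
    ic_labels: list = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.unmixing.shape[0]
        if self.ic_labels is None:
            self.ic_labels = [f"IC{i + 1:03d}" for i in range(n)]
        err = np.abs(self.unmixing @ self.mixing - np.eye(n)).max()
        if err > 1e-6:
            raise FitError(f"W @ A deviates from identity by {err:g}")

    @property
    def n_components(self):
        return self.unmixing.shape[0]

    def activations(self, data):
        return self.unmixing @ data

    def good_ics(self):
        return [i for i in range(self.n_components) if i not in self.artifact_flags]


# ---------------------------------------------------------------------------
# Gradient artifact
# ---------------------------------------------------------------------------

def subtract_gradient_template(rec, scan_code="scan", window_volumes=21):
    """Remove the MR gradient artifact by sliding-average template subtraction.

    For every channel and every volume epoch (between consecutive scan
    triggers), the average of the ``window_volumes`` surrounding epochs
    (centered window, truncated at the run edges) is subtracted.
    """
    trig = rec.trigger_samples(scan_code)
    if len(trig) < window_volumes:
        raise TimingError(
            f"need >= {window_volumes} scan triggers, got {len(trig)}"
        )
    spacing = np.diff(trig)
    if spacing.max() - spacing.min() > 1:
        raise TimingError("scan trigger spacing varies by more than 1 sample")
    period = int(round(spacing.mean()))

    n_epochs = len(trig)
    epochs = np.zeros((n_epochs, rec.n_channels, period))
    valid = np.zeros(n_epochs, dtype=bool)
    for i, s in enumerate(trig):
        if s + period <= rec.n_samples:
            epochs[i] = rec.data[:, s:s + period]
            valid[i] = True

    out = rec.data.copy()
    half = window_volumes // 2
    idx_valid = np.flatnonzero(valid)
    for i in idx_valid:
        lo = max(0, i - half)
        hi = min(n_epochs, i + half + 1)
        sel = idx_valid[(idx_valid >= lo) & (idx_valid < hi)]
        template = epochs[sel].mean(axis=0)
        s = trig[i]
        out[:, s:s + period] -= template
    return Recording(
        data=out,
        sfreq=rec.sfreq,
        channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds),
        triggers=list(rec.triggers),
    )


# ---------------------------------------------------------------------------
# Filtering / downsampling
# ---------------------------------------------------------------------------

def bandpass_downsample(rec, low=0.2, high=48.0, out_sfreq=100.0, order=4):
    """Zero-phase Butterworth bandpass followed by decimation.

    ``high`` must stay below the output Nyquist so the bandpass itself
    provides the anti-alias margin; trigger samples are remapped to the new
    rate.
    """
    if out_sfreq > rec.sfreq:
        raise ConfigError("cannot upsample: out_sfreq > recording sfreq")
    if high >= out_sfreq / 2:
        raise ConfigError("bandpass high edge must be below the output Nyquist")
    nyq = rec.sfreq / 2
    sos = signal.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    filt = signal.sosfiltfilt(sos, rec.data, axis=1)

    if abs(out_sfreq - rec.sfreq) < 1e-9:
        data = filt
    else:
        from fractions import Fraction

        frac = Fraction(out_sfreq / rec.sfreq).limit_denominator(1000)
        data = signal.resample_poly(filt, frac.numerator, frac.denominator, axis=1)
    ratio = out_sfreq / rec.sfreq
    n_out = data.shape[1]
    triggers = [
        (min(int(round(s * ratio)), n_out - 1), c) for s, c in rec.triggers
    ]
    return Recording(
        data=data,
        sfreq=out_sfreq,
        channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds),
        triggers=triggers,
    )


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

def fit_unmixing(rec, seed, picks=None, max_iter=500):
    """Fit a square extended-infomax unmixing matrix on continuous data.

    The data are mean-centered and PCA-whitened, extended infomax (sub- and
    super-Gaussian sources allowed) is run on the whitened series, and the
    whitener is folded into the returned unmixing matrix, so
    ``W @ data`` gives IC activations directly.  Deterministic given ``seed``.
    If the data are rank deficient the decomposition is reduced to the
    numerical rank with a warning.

    Scale convention: mixing columns are normalized to unit norm, so each
    IC activation is expressed in microvolt-equivalent units (its
    channel-space contribution), not in whitened unit-variance units.  This
    matters downstream when amplitude vectors of several ICs are summed.
    """
    from mne.preprocessing import infomax

    if picks is None:
        picks = list(range(rec.n_channels))
    X = rec.data[picks]
    n_ch, n_samp = X.shape
    if n_samp < 4 * n_ch**2:
        logger.warning(
            "few samples for ICA: %d samples for %d channels", n_samp, n_ch
        )
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    cov = (Xc @ Xc.T) / n_samp
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > evals[0] * 1e-10))
    if rank < n_ch:
        logger.warning("rank-deficient data: reducing %d -> %d components", n_ch, rank)
    evals, evecs = evals[:rank], evecs[:, :rank]
    whitener = (evecs / np.sqrt(evals)).T  # (rank, n_ch)
    Y = whitener @ Xc

    W_info = infomax(
        Y.T, extended=True, max_iter=max_iter, rng=int(seed) % (2**32),
        verbose="error",
    )
    W = W_info @ whitener
    A = np.linalg.pinv(W)
    norms = np.linalg.norm(A, axis=0)
    A = A / norms
    W = W * norms[:, None]
    return Decomposition(
        unmixing=W,
        mixing=A,
        metadata={"seed": int(seed), "rank": rank, "picks": list(map(int, picks)),
                  "channel_mean": mean.ravel().tolist()},
    )


# ---------------------------------------------------------------------------
# Artifact event detection
# ---------------------------------------------------------------------------

def detect_artifact_events(
    rec, channel_kind, theta=0.6, refractory_s=None, band=(0.5, 20.0),
    template_halfwidth_s=0.15,
):
    """Detect heartbeats (ECG) or blinks (EOG) on an auxiliary channel.

    Provisional peaks are found on the bandpassed channel, a time-domain
    template is averaged around them, and the final events are local maxima
    of the template matched filter exceeding ``theta`` times its maximum,
    with a refractory period (0.4 s heartbeat / 0.25 s blink by default).
    Returns event times in seconds.
    """
    if refractory_s is None:
        refractory_s = 0.4 if channel_kind == "ecg" else 0.25
    chans = rec.channels_of_kind(channel_kind)
    if not chans:
        raise DetectionError(f"no channel of kind {channel_kind!r}")
    x = rec.data[chans[0]].astype(float)
    if np.ptp(x) == 0:
        raise DetectionError("flat auxiliary channel")
    nyq = rec.sfreq / 2
    sos = signal.butter(
        2, [band[0] / nyq, min(band[1], 0.95 * nyq) / nyq], btype="band", output="sos"
    )
    xf = signal.sosfiltfilt(sos, x)
    mad = np.median(np.abs(xf - np.median(xf))) / 0.6745
    if mad == 0:
        raise DetectionError("no variability in auxiliary channel")
    dist = max(1, int(round(refractory_s * rec.sfreq)))
    peaks, _ = signal.find_peaks(xf, prominence=3.0 * mad, distance=dist)
    if len(peaks) < 10:
        raise DetectionError(f"only {len(peaks)} provisional peaks; signal too weak")

    hw = int(round(template_halfwidth_s * rec.sfreq))
    segs = [
        xf[p - hw:p + hw + 1]
        for p in peaks
        if p - hw >= 0 and p + hw + 1 <= len(xf)
    ]
    template = np.mean(segs, axis=0)
    template = template - template.mean()
    m = signal.correlate(xf, template, mode="same")
    m /= np.abs(m).max()
    final, _ = signal.find_peaks(m, height=theta, distance=dist)
    return final / rec.sfreq


# ---------------------------------------------------------------------------
# Artifact IC flagging
# ---------------------------------------------------------------------------

def locked_average_rms(acts, event_samples, pre, post):
    """RMS of the event-locked average of each IC over a peri-event window."""
    n_ic, n_samp = acts.shape
    keep = [s for s in event_samples if s - pre >= 0 and s + post <= n_samp]
    if not keep:
        return np.zeros(n_ic)
    seg = np.stack([acts[:, s - pre:s + post] for s in keep])  # ev x ic x t
    avg = seg.mean(axis=0)
    return np.sqrt((avg**2).mean(axis=1))


def flag_artifact_ics(
    dec, rec, event_times_s, reason, n_null=200, seed=0,
    window_s=(-0.3, 0.3), percentile=99.0, min_ratio=2.0,
):
    """Flag ICs that load on the event-locked average.

    The locked-average RMS of each IC is compared with the distribution of
    the same statistic over ``n_null`` circularly shifted surrogate event
    sets.  An IC is flagged with ``reason`` when its RMS exceeds the
    surrogate ``percentile`` AND exceeds ``min_ratio`` times the surrogate
    median: the first condition is the significance test, the second an
    effect-size floor that spares ICs carrying only trace leakage of the
    artifact (a square decomposition never separates perfectly, so nearly
    every IC is weakly but significantly locked).  Returns the updated
    ``artifact_flags`` dict.
    """
    if n_null < 50:
        raise ConfigError("n_null must be >= 50 for a usable null")
    if len(event_times_s) < 20:
        raise ConfigError("need >= 20 artifact events")
    rng = np.random.default_rng(seed)
    acts = dec.activations(rec.data)
    n_samp = acts.shape[1]
    pre = int(round(-window_s[0] * rec.sfreq))
    post = int(round(window_s[1] * rec.sfreq))
    samples = np.round(np.asarray(event_times_s) * rec.sfreq).astype(int)

    observed = locked_average_rms(acts, samples, pre, post)
    null = np.zeros((n_null, dec.n_components))
    for k in range(n_null):
        shift = rng.integers(n_samp // 4, 3 * n_samp // 4)
        null[k] = locked_average_rms(acts, (samples + shift) % n_samp, pre, post)
    thresh = np.maximum(
        np.percentile(null, percentile, axis=0),
        min_ratio * np.median(null, axis=0),
    )
    for i in np.flatnonzero(observed > thresh):
        dec.artifact_flags.setdefault(int(i), reason)
    return dec.artifact_flags


def backproject_excluding(dec, rec, exclude=None):
    """Channel-space data with the flagged (or given) ICs removed.

    Used only for the ERP comparison path; the IC path works on raw IC
    activations minus flagged ICs.
    """
    if exclude is None:
        exclude = sorted(dec.artifact_flags)
    acts = dec.activations(rec.data)
    acts[list(exclude)] = 0.0
    clean = dec.mixing @ acts
    return Recording(
        data=clean,
        sfreq=rec.sfreq,
        channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds),
        triggers=list(rec.triggers),
    )
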