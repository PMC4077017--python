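"""Per-trial amplitude extraction from selected IC ranges or fixed ERP windows.

Both paths operate on the same epoch geometry.  The IC path averages each
trial's IC activation over the selected latency range, flips the sign where
needed so the Nogo-dominant deflection is positive, and sums across all
ranges selected for the same analysis window.  The ERP path measures plain
window means (N2: 280-340 ms, P3: 350-570 ms) at one electrode (Cz) on
artifact-corrected data re-referenced to the TP9/TP10 average, keeping the
raw sign.  Amplitudes are extracted for every epoched trial - Go, Nogo and
errors alike - because the regressor must cover the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Recording
from .icselect import SelectionError


class FeatureError(RuntimeError):
    pass


class ChannelError(KeyError):
    pass


@dataclass
class AmplitudeVector:
    """One polarity-corrected amplitude per retained stimulus event."""

    values: np.ndarray
    onsets_s: np.ndarray
    label: str
    run_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.values.shape != self.onsets_s.shape:
            raise FeatureError("values and onsets must align")
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("non-finite amplitude values")


def _range_mean(ep, ic, t_on, t_off):
    # snap the half-open window to the sample grid to avoid fp edge effects
    i0 = int(round((t_on - ep.times[0]) * ep.sfreq))
    i1 = int(round((t_off - ep.times[0]) * ep.sfreq))
    i0 = max(i0, 0)
    i1 = min(i1, len(ep.times))
    if i1 <= i0:
        raise FeatureError(f"empty sample range [{t_on}, {t_off})")
    return ep.values[:, ic, i0:i1].mean(axis=1)


def single_trial_amplitudes(ep, selection, window_tag, events, run_id=""):
    """Summed polarity-corrected single-trial means over selected ranges.

    For each trial and each selected (ic, range): the mean of the IC epoch
    over [t_on, t_off) multiplied by the range's polarity; summed over all
    ranges tagged with ``window_tag``.
    """
    ranges = [r for r in selection if window_tag in r.windows]
    if not ranges:
        raise SelectionError(f"no selected ranges for window {window_tag!r}")
    total = np.zeros(ep.n_trials)
    for r in ranges:
        total += r.polarity * _range_mean(ep, r.ic, r.t_on, r.t_off)
    return AmplitudeVector(
        values=total,
        onsets_s=events.onsets[ep.trial_rows],
        label=window_tag,
        run_id=run_id,
    )


def rereference(rec, refs=("TP9", "TP10")):
    """Subtract the mean of the reference channels from every scalp channel."""
    try:
        ref_idx = [rec.channel_labels.index(r) for r in refs]
    except ValueError as exc:
        raise ChannelError(f"missing reference channel: {exc}") from exc
    ref = rec.data[ref_idx].mean(axis=0)
    data = rec.data.copy()
    for i, kind in enumerate(rec.channel_kinds):
        if kind == "scalp":
            data[i] = data[i] - ref
    return Recording(
        data=data,
        sfreq=rec.sfreq,
        channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds),
        triggers=list(rec.triggers),
    )


ERP_WINDOWS = {"N2": (0.280, 0.340), "P3": (0.350, 0.570)}


def erp_amplitudes(ep, channel_labels, events, electrode="Cz", component="N2",
                   window=None, invert=False, run_id=""):
    """Per-trial mean amplitude in a fixed ERP window at one electrode.

    No polarity inversion by default (signed regressors); ``invert`` flips
    the sign, e.g. for the negative-going N2.
    """
    lo, hi = ERP_WINDOWS[component] if window is None else window
    if not (ep.times[0] <= lo < hi <= ep.times[-1] + 1.0 / ep.sfreq):
        raise FeatureError(f"window [{lo}, {hi}) outside the epoch span")
    try:
        ch = list(channel_labels).index(electrode)
    except ValueError as exc:
        raise ChannelError(f"electrode {electrode!r} not present") from exc
    vals = _range_mean(ep, ch, lo, hi)
    if invert:
        vals = -vals
    return AmplitudeVector(
        values=vals,
        onsets_s=events.onsets[ep.trial_rows],
        label=component,
        run_id=run_id,
    )


def median_rt(events):
    """Median correct-Go response time in seconds."""
    t = events.table
    rts = t.loc[
        (t["trial_type"] == "Go") & (t["response"] == "correct"), "response_time"
    ].to_numpy(float)
    rts = rts[np.isfinite(rts)]
    if len(rts) == 0:
        raise SelectionError("no correct Go trials with RT")
    return float(np.median(rts))
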