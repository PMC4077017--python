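"""Data-driven classification and selection of task-related ICs.

The core procedure: epoch IC activations (-200..1000 ms, baseline-corrected
on the 200 ms pre-stimulus interval), compute pointwise means and unbiased
variances per condition, form pointwise t statistics (Welch two-sample
Nogo vs Go, or one-sample against baseline for visual responses), and
standardize them to per-trial signal-to-noise Z scores,

    Z = t / sqrt(n_ref),   n_ref = epochs in the smaller condition,

so that the fixed threshold |Z| > 0.275 corresponds to a two-sided p = 0.01
two-sample t at df = 89 (the 90 Nogo trials of a 300-trial run).  Maximal
contiguous above-threshold excursions become latency ranges; each range gets
a polarity (sign of the condition average with the larger absolute
amplitude), Go-dominant ranges are discarded, and a range survives only if
it rises above threshold after the start and falls below before the end of
an analysis window: early = [200 ms, median RT], late = [RT-100, RT+300] ms,
visual = [90, 140] ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("eegfmri")

Z_THRESHOLD = 0.275  # two-sided p = 0.01, two-sample t, df = 89

CONDITIONS = ("go_correct", "nogo_correct", "omission", "commission")


class StatisticError(ValueError):
    pass


class SelectionError(RuntimeError):
    """No usable trials/ranges for a required selection."""


@dataclass
class EpochSet:
    """trials x units x time array of baseline-corrected epochs.

    ``units`` are ICs or channels.  ``trial_rows`` maps each epoch back to
    its row in the event table; ``conditions`` holds the per-trial label.
    """

    values: np.ndarray
    times: np.ndarray
    sfreq: float
    trial_rows: np.ndarray
    conditions: np.ndarray

    @property
    def n_trials(self):
        return self.values.shape[0]

    @property
    def n_units(self):
        return self.values.shape[1]

    def in_condition(self, condition):
        if condition == "pooled_correct":
            m = np.isin(self.conditions, ["go_correct", "nogo_correct"])
        else:
            m = self.conditions == condition
        return self.values[m]


@dataclass
class ConditionStats:
    """Pointwise mean and unbiased variance of one condition's epochs."""

    mean: np.ndarray  # units x time
    var: np.ndarray
    n: int
    condition: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise StatisticError("need >= 2 epochs per condition")


@dataclass
class ZSeries:
    """Pointwise standardized reliability statistic per unit."""

    z: np.ndarray  # units x time
    times: np.ndarray
    mode: str  # "two_sample" | "one_sample"
    n_ref: int
    df: int


@dataclass
class LatencyRange:
    """One above-threshold excursion of |Z| for one IC/unit."""

    ic: int
    t_on: float
    t_off: float
    polarity: int
    dominant_condition: str = "n/a"
    windows: tuple = ()
    peak_abs_z: float = np.nan

    def __post_init__(self):
        if not self.t_on < self.t_off:
            raise StatisticError("t_on must precede t_off")
        if self.polarity not in (-1, 1):
            raise StatisticError("polarity must be +1 or -1")


@dataclass
class AnalysisWindows:
    """Participant-specific analysis windows (seconds post-stimulus)."""

    early: tuple
    late: tuple
    visual: tuple = (0.090, 0.140)
    z_threshold: float = Z_THRESHOLD

    def __post_init__(self):
        if self.early[0] >= self.early[1]:
            raise StatisticError("empty early window (median RT <= 200 ms)")
        if self.z_threshold <= 0:
            raise StatisticError("z_threshold must be positive")

    @classmethod
    def from_median_rt(cls, median_rt_s, z_threshold=Z_THRESHOLD):
        return cls(
            early=(0.200, median_rt_s),
            late=(median_rt_s - 0.100, median_rt_s + 0.300),
            z_threshold=z_threshold,
        )

    def items(self):
        return {"early": self.early, "late": self.late, "visual": self.visual}.items()


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_units(
    timecourses, sfreq, events, window=(-0.2, 1.0), baseline=(-0.2, 0.0)
):
    """Segment continuous unit time courses around stimulus onsets.

    1200 ms epochs starting 200 ms before onset at 100 Hz give 120 samples;
    the per-trial mean over the baseline interval is subtracted.  Trials too
    close to the run edges are dropped with a log entry.
    """
    timecourses = np.atleast_2d(np.asarray(timecourses, dtype=float))
    n_units, n_samples = timecourses.shape
    t0, t1 = window
    n_times = int(round((t1 - t0) * sfreq))
    times = t0 + np.arange(n_times) / sfreq
    rel0 = int(round(t0 * sfreq))

    conditions = events.condition()
    vals, rows, conds = [], [], []
    for row, onset in enumerate(events.onsets):
        s0 = int(round(onset * sfreq)) + rel0
        if s0 < 0 or s0 + n_times > n_samples:
            logger.info("dropping trial %d at %.3f s: epoch outside run", row, onset)
            continue
        vals.append(timecourses[:, s0:s0 + n_times])
        rows.append(row)
        conds.append(conditions[row])
    if not vals:
        raise SelectionError("no epochable trials")
    values = np.stack(vals)  # trials x units x time
    bmask = (times >= baseline[0]) & (times < baseline[1])
    values = values - values[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochSet(
        values=values,
        times=times,
        sfreq=sfreq,
        trial_rows=np.asarray(rows, dtype=int),
        conditions=np.asarray(conds, dtype=object),
    )


# ---------------------------------------------------------------------------
# Pointwise statistics
# ---------------------------------------------------------------------------

def condition_stats(ep, condition):
    """Pointwise mean and unbiased variance of one condition's epochs."""
    x = ep.in_condition(condition)
    if x.shape[0] < 2:
        raise StatisticError(
            f"condition {condition!r} has {x.shape[0]} epochs, need >= 2"
        )
    return ConditionStats(
        mean=x.mean(axis=0),
        var=x.var(axis=0, ddof=1),
        n=x.shape[0],
        condition=condition,
    )


def pointwise_z(a, b=None, times=None):
    """Pointwise t statistic standardized to a per-trial SNR Z score.

    Two-sample (Welch): t = (m_a - m_b) / sqrt(v_a/n_a + v_b/n_b);
    one-sample: t = m / sqrt(v/n), against 0 (epochs are baseline-corrected).
    Z = t / sqrt(n_ref) with n_ref the smaller condition's epoch count, and
    df = n_ref - 1 recorded conservatively.
    """
    if b is not None:
        num = a.mean - b.mean
        den = np.sqrt(a.var / a.n + b.var / b.n)
        n_ref = min(a.n, b.n)
        mode = "two_sample"
    else:
        num = a.mean
        den = np.sqrt(a.var / a.n)
        n_ref = a.n
        mode = "one_sample"
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    t[(den == 0) & (num == 0)] = 0.0
    if np.isinf(t).any():
        logger.warning("zero variance with nonzero difference: Z = +/-inf flagged")
    z = t / np.sqrt(n_ref)
    return ZSeries(z=z, times=times, mode=mode, n_ref=n_ref, df=n_ref - 1)


# ---------------------------------------------------------------------------
# Latency ranges
# ---------------------------------------------------------------------------

def _runs_above(mask):
    """(start, end) index pairs of maximal True runs, end exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def extract_ranges(zs, stats_a, stats_b=None, threshold=Z_THRESHOLD, mode="nogo"):
    """Maximal contiguous |Z| > threshold excursions with polarity rules.

    Only the post-stimulus span (t >= 0) is scanned.  Each excursion is
    reported as half-open [t_on, t_off): t_on is the first above-threshold
    sample time, t_off the first below-threshold sample time after the run.

    mode="nogo": ``stats_a`` is the Nogo average, ``stats_b`` the Go average;
    the dominant condition is the one with the larger mean absolute amplitude
    over the range, the polarity is the sign of the dominant average, and
    Go-dominant ranges are discarded.  mode="visual": ``stats_a`` is the
    pooled average; its sign over the range is the polarity, no dominance
    filter.
    """
    times = zs.times
    dt = float(np.median(np.diff(times)))
    post = times >= -1e-9
    tpost = times[post]
    zpost = zs.z[:, post]
    a_post = stats_a.mean[:, post]
    b_post = stats_b.mean[:, post] if stats_b is not None else None

    out = []
    for ic in range(zpost.shape[0]):
        above = np.abs(zpost[ic]) > threshold
        for i0, i1 in _runs_above(above):
            t_on = tpost[i0]
            t_off = tpost[i1] if i1 < len(tpost) else tpost[-1] + dt
            sl = slice(i0, i1)
            peak = float(np.abs(zpost[ic, sl]).max())
            m_a = float(a_post[ic, sl].mean())
            if mode == "nogo":
                m_b = float(b_post[ic, sl].mean())
                if abs(m_b) > abs(m_a):
                    continue  # Go-dominant: discard
                dominant = "Nogo"
                pol = 1 if m_a >= 0 else -1
            else:
                dominant = "n/a"
                pol = 1 if m_a >= 0 else -1
            out.append(
                LatencyRange(
                    ic=ic, t_on=float(t_on), t_off=float(t_off), polarity=pol,
                    dominant_condition=dominant, peak_abs_z=peak,
                )
            )
    return out


def select_for_windows(ranges, windows, which=("early", "late", "visual")):
    """Keep ranges wholly contained in an analysis window; tag all that fit.

    A range is tagged with window w iff w.start <= t_on and t_off <= w.end;
    ranges inside the early/late overlap carry both tags; untagged ranges
    are dropped.
    """
    out = []
    for r in ranges:
        tags = tuple(
            name
            for name, (lo, hi) in windows.items()
            if name in which and lo <= r.t_on + 1e-9 and r.t_off <= hi + 1e-9
        )
        if tags:
            out.append(
                LatencyRange(
                    ic=r.ic, t_on=r.t_on, t_off=r.t_off, polarity=r.polarity,
                    dominant_condition=r.dominant_condition, windows=tags,
                    peak_abs_z=r.peak_abs_z,
                )
            )
    return out


def select_nogo_ics(ep, windows, threshold=None, exclude_ics=()):
    """Full Nogo-related selection on an epoched IC set.

    Correct trials only enter the classification; flagged artifact ICs are
    excluded from the candidate list.  Returns the tagged ranges.
    """
    thr = windows.z_threshold if threshold is None else threshold
    s_nogo = condition_stats(ep, "nogo_correct")
    s_go = condition_stats(ep, "go_correct")
    zs = pointwise_z(s_nogo, s_go, times=ep.times)
    ranges = extract_ranges(zs, s_nogo, s_go, threshold=thr, mode="nogo")
    ranges = [r for r in ranges if r.ic not in set(exclude_ics)]
    return select_for_windows(ranges, windows, which=("early", "late"))


def select_visual_ics(ep, windows, threshold=None, exclude_ics=()):
    """Visual-response selection: pooled correct epochs against baseline."""
    thr = windows.z_threshold if threshold is None else threshold
    pooled = condition_stats(ep, "pooled_correct")
    zs = pointwise_z(pooled, times=ep.times)
    ranges = extract_ranges(zs, pooled, threshold=thr, mode="visual")
    ranges = [r for r in ranges if r.ic not in set(exclude_ics)]
    return select_for_windows(ranges, windows, which=("visual",))
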