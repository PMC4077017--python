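"""EEG-derived and onset fMRI regressors.

Pipeline order (fixed): cubic-smoothing-spline resampling of the per-trial
amplitude vector (1 Hz trial rate) to the acquisition grid (1/2.25 Hz),
normalization to unit inter-quartile range, convolution with the canonical
double-gamma HRF, and orthogonalization with respect to the Go/Nogo/Errors
onset regressors (plus intercept) so the EEG column carries only
trial-to-trial variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("eegfmri")

HRF_OVERSAMPLING = 16


class InterpolationError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class Regressor:
    """One design-matrix column sampled at the analyzed volume times."""

    values: np.ndarray
    name: str
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in regressor {self.name!r}")


@dataclass
class HRFSpec:
    """Canonical double-gamma HRF (SPM parametrization)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    ratio: float = 6.0
    length_s: float = 32.0

    def kernel(self, tr_s, oversampling=HRF_OVERSAMPLING):
        """Kernel sampled at tr/oversampling; starts at 0 at t = 0."""
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        if (self.peak_delay_s, self.undershoot_delay_s, self.ratio,
                self.length_s) != (6.0, 16.0, 6.0, 32.0):
            from scipy.stats import gamma

            dt = tr_s / oversampling
            t = np.arange(0, self.length_s, dt)
            k = (gamma.pdf(t, self.peak_delay_s)
                 - gamma.pdf(t, self.undershoot_delay_s) / self.ratio)
            return k / k.sum()
        return spm_hrf(tr_s, oversampling=oversampling, time_length=self.length_s)


def resample_to_scans(amp, scan_times, lam=None):
    """Cubic smoothing spline through (onset, value), evaluated at scan times.

    ``lam`` is the smoothing parameter (None = generalized cross-validation,
    0 = interpolating spline).  Extrapolation beyond the first/last trial is
    clamped to the boundary values.
    """
    from scipy.interpolate import make_smoothing_spline

    x = np.asarray(amp.onsets_s, dtype=float)
    y = np.asarray(amp.values, dtype=float)
    if len(x) < 4:
        raise InterpolationError(f"need >= 4 support points, got {len(x)}")
    spline = make_smoothing_spline(x, y, lam=lam)
    t = np.clip(np.asarray(scan_times, dtype=float), x[0], x[-1])
    return spline(t)


def normalize_iqr(values):
    """Median-center and scale to unit inter-quartile range."""
    values = np.asarray(values, dtype=float)
    q25, q75 = np.percentile(values, [25, 75])
    iqr = q75 - q25
    if iqr <= 0:
        raise NormalizationError("IQR is zero; cannot normalize")
    return (values - np.median(values)) / iqr


def hrf_convolve(values, tr_s, hrf=None, name="eeg", provenance=""):
    """Causal convolution of a scan-grid series with the HRF kernel.

    The kernel is sampled 16x oversampled then decimated to the scan grid;
    the output is truncated to the input length.
    """
    hrf = hrf or HRFSpec()
    fine = hrf.kernel(tr_s)
    kernel = fine[::HRF_OVERSAMPLING]
    out = np.convolve(np.asarray(values, dtype=float), kernel)[: len(values)]
    return Regressor(values=out, name=name, provenance=provenance)


def build_onset_regressors(events, scan_times, tr_s, hrf=None):
    """HRF-convolved delta trains at Go / Nogo / Errors onsets.

    Deltas (duration 0) are placed on a 16x oversampled grid, convolved with
    the HRF, and sampled at the analyzed volume times.  Conditions with zero
    events are dropped with a warning.
    """
    hrf = hrf or HRFSpec()
    cond = events.condition()
    groups = {
        "Go": events.onsets[cond == "go_correct"],
        "Nogo": events.onsets[cond == "nogo_correct"],
        "Errors": events.onsets[np.isin(cond, ["omission", "commission"])],
    }
    scan_times = np.asarray(scan_times, dtype=float)
    dt = tr_s / HRF_OVERSAMPLING
    t0 = min(scan_times[0], 0.0)
    n_fine = int(np.ceil((scan_times[-1] - t0) / dt)) + 1
    kernel = hrf.kernel(tr_s)
    vol_idx = np.round((scan_times - t0) / dt).astype(int)

    out = {}
    for name, onsets in groups.items():
        if len(onsets) == 0:
            logger.warning("condition %s has zero events; column dropped", name)
            continue
        train = np.zeros(n_fine)
        idx = np.round((onsets - t0) / dt).astype(int)
        ok = (idx >= 0) & (idx < n_fine)
        np.add.at(train, idx[ok], 1.0)
        conv = np.convolve(train, kernel)[:n_fine]
        out[name] = Regressor(
            values=conv[vol_idx], name=name, provenance=f"onset: {name}"
        )
    return out


def orthogonalize(reg, nuisance, rtol=1e-10):
    """Residual of projecting a regressor onto span(nuisance + intercept).

    Dot products of the result with every nuisance column are ~0, so the
    nuisance betas in a subsequent GLM are unchanged by including it
    (Frisch-Waugh).  Rank-deficient nuisance sets fall back to the
    pseudo-inverse with a log entry.
    """
    cols = [np.asarray(n.values if isinstance(n, Regressor) else n, float)
            for n in nuisance]
    X = np.column_stack(cols + [np.ones(len(reg.values))])
    rank = np.linalg.matrix_rank(X, tol=rtol * np.abs(X).max() * max(X.shape))
    if rank < X.shape[1]:
        logger.warning("rank-deficient nuisance set; using pseudo-inverse")
    beta, *_ = np.linalg.lstsq(X, reg.values, rcond=None)
    resid = reg.values - X @ beta
    return Regressor(
        values=resid, name=reg.name, provenance=reg.provenance + " (orthogonalized)"
    )


def build_eeg_regressor(
    amp, events, scan_times, tr_s, hrf=None, lam=None, orthogonalize_to_onsets=True,
):
    """Full EEG-regressor pipeline: resample -> IQR -> HRF -> orthogonalize."""
    vals = resample_to_scans(amp, scan_times, lam=lam)
    vals = normalize_iqr(vals)
    reg = hrf_convolve(vals, tr_s, hrf=hrf, name=f"eeg_{amp.label}",
                       provenance=f"eeg: {amp.label}")
    onsets = build_onset_regressors(events, scan_times, tr_s, hrf=hrf)
    if orthogonalize_to_onsets:
        reg = orthogonalize(reg, list(onsets.values()))
    return reg, onsets
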