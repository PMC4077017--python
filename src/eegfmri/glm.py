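"""Voxelwise first-level GLM, run averaging, group t-tests, cluster extent.

The first-level design holds Go/Nogo/Errors onset regressors, one EEG
regressor, a discrete-cosine high-pass set (128 s cutoff) and an intercept;
ordinary least squares per voxel yields beta and t images for the EEG
column.  The two runs' contrast images are averaged into one subject image;
group maps are voxelwise one-sample or paired t statistics thresholded at an
uncorrected voxel p (default 0.005) with a cluster-extent filter (default
k = 20 voxels, 26-connectivity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger("eegfmri")


class DesignError(ValueError):
    pass


class GridError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Named columns sampled at the analyzed volumes."""

    matrix: np.ndarray
    names: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise DesignError("column names must match matrix width")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            corr = np.corrcoef(self.matrix.T)
            np.fill_diagonal(corr, 0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise DesignError(
                f"rank-deficient design; most collinear columns: "
                f"{self.names[i]!r} and {self.names[j]!r}"
            )

    @property
    def n_volumes(self):
        return self.matrix.shape[0]


@dataclass
class StatMap:
    """Voxelwise beta/t/Z images for one contrast."""

    beta: np.ndarray
    t: np.ndarray
    z: np.ndarray
    df: int
    contrast: str = ""
    mask: np.ndarray = None


def highpass_basis(n_vols, tr_s, cutoff_s=128.0):
    """Discrete cosine high-pass set spanning periods above the cutoff.

    Number of columns = floor(2 * n * TR / cutoff), constant excluded;
    columns are mutually orthogonal.
    """
    if n_vols < 8:
        raise DesignError("need >= 8 volumes for a high-pass basis")
    k_max = int(np.floor(2.0 * n_vols * tr_s / cutoff_s))
    n = np.arange(n_vols)
    cols = [
        np.sqrt(2.0 / n_vols) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_vols))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_vols, 0))


def build_design(onset_regs, eeg_reg, n_vols, tr_s, cutoff_s=128.0):
    """Assemble the first-level design matrix with high-pass set + intercept."""
    cols, names = [], []
    for name, reg in onset_regs.items():
        cols.append(reg.values)
        names.append(name)
    if eeg_reg is not None:
        cols.append(eeg_reg.values)
        names.append(eeg_reg.name)
    hp = highpass_basis(n_vols, tr_s, cutoff_s)
    for k in range(hp.shape[1]):
        cols.append(hp[:, k])
        names.append(f"cosine{k + 1:02d}")
    cols.append(np.ones(n_vols))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=names)


def fit_first_level(bold, design, mask=None, contrast_col=None):
    """Per-voxel OLS; beta/t/Z images for one column (default: the EEG one).

    ``bold`` is a VolumeSeries; only its analyzed volumes enter the fit.
    """
    Y4 = bold.analyzed()
    if Y4.shape[3] != design.n_volumes:
        raise DesignError(
            f"design rows ({design.n_volumes}) != analyzed volumes ({Y4.shape[3]})"
        )
    if mask is None:
        mask = np.ones(Y4.shape[:3], dtype=bool)
    if not mask.any():
        raise DesignError("empty mask")
    if contrast_col is None:
        eeg = [n for n in design.names if n.startswith("eeg")]
        contrast_col = eeg[0] if eeg else design.names[0]
    ci = design.names.index(contrast_col)

    X = design.matrix
    n, p = X.shape
    df = n - p
    Y = Y4[mask].T  # volumes x voxels
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv_cc = (pinv @ pinv.T)[ci, ci]
    se = np.sqrt(sigma2 * xtx_inv_cc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[ci] / se
    t[se == 0] = 0.0

    shape = Y4.shape[:3]
    bmap = np.zeros(shape)
    tmap = np.zeros(shape)
    bmap[mask] = beta[ci]
    tmap[mask] = t
    zmap = np.zeros(shape)
    zmap[mask] = t_to_z(t, df)
    return StatMap(beta=bmap, t=tmap, z=zmap, df=df, contrast=contrast_col, mask=mask)


def t_to_z(t, df):
    """Map t values to standard-normal deviates, tail-stable."""
    t = np.asarray(t, dtype=float)
    z = np.where(
        t >= 0,
        stats.norm.isf(stats.t.sf(t, df)),
        stats.norm.ppf(stats.t.cdf(t, df)),
    )
    return np.clip(z, -40, 40)


def average_runs(images):
    """Voxelwise arithmetic mean of per-run contrast images."""
    arrs = [np.asarray(im, dtype=float) for im in images]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise GridError("run images are not on the same grid")
    return np.mean(arrs, axis=0)


def group_stats(subject_images, mode="one_sample", paired_with=None, mask=None):
    """Voxelwise group t-map across subjects.

    one_sample: t = mean / SE, df = n - 1.  paired: one-sample t on the
    voxelwise differences ``subject_images - paired_with`` (exact identity).
    """
    imgs = [np.asarray(im, dtype=float) for im in subject_images]
    if mode == "paired":
        if paired_with is None or len(paired_with) != len(imgs):
            raise PairingError("paired mode needs two aligned image lists")
        imgs = [a - np.asarray(b, float) for a, b in zip(imgs, paired_with)]
    n = len(imgs)
    if n < 3:
        raise PairingError("need >= 3 subjects")
    data = np.stack(imgs)
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t[se == 0] = 0.0
    df = n - 1
    if mask is None:
        mask = np.ones(mean.shape, dtype=bool)
    return StatMap(
        beta=mean, t=t, z=t_to_z(t, df), df=df,
        contrast=mode, mask=mask,
    )


def cluster_threshold(statmap, p_voxel=0.005, k=20, connectivity=26, sign=1):
    """Supra-threshold clusters with an extent filter.

    Voxel threshold: one-sided p (directional contrasts); ``sign`` selects
    the tail.  Clusters smaller than ``k`` voxels (26-connectivity by
    default) are removed.  Returns a table of (size, peak t, peak indices).
    """
    t_crit = stats.t.isf(p_voxel, statmap.df)
    supra = (sign * statmap.t > t_crit) & statmap.mask
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }[connectivity]
    labels, n_lab = ndimage.label(supra, structure=structure)
    rows = []
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < k:
            continue
        tvals = sign * statmap.t[labels == lab]
        peak_local = np.argmax(tvals)
        peak = vox[peak_local]
        rows.append({
            "size": len(vox),
            "peak_t": float(sign * tvals[peak_local]),
            "peak_x": int(peak[0]), "peak_y": int(peak[1]), "peak_z": int(peak[2]),
        })
    rows.sort(key=lambda r: -r["size"])
    return pd.DataFrame(rows, columns=["size", "peak_t", "peak_x", "peak_y", "peak_z"])


def smooth_volumes(data4d, fwhm_vox):
    """Optional isotropic Gaussian pre-smoothing (FWHM in voxels)."""
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = np.empty_like(data4d, dtype=float)
    for j in range(data4d.shape[3]):
        out[..., j] = ndimage.gaussian_filter(data4d[..., j], sigma)
    return out
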