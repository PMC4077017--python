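"""Readers/writers for the standard formats the pipeline touches.

EEG comes in as BrainVision (.vhdr/.vmrk/.eeg) or EDF and lives in memory as
a :class:`Recording` (channels x samples, microvolts).  Trial structure lives
in a tab-separated events table (BIDS-style columns).  BOLD volumes are
NIfTI-1.  Intermediate results (recordings, decompositions) are persisted in
an HDF5 run container.

Conventions
-----------
* all onsets are seconds from run start; sample indices are 0-based
* intervals are half-open ``[start, end)``
* the events file is the single source of truth for trial typing; trigger
  codes in the EEG are cross-checked and mismatches logged, never fatal
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("eegfmri")

EVENT_COLUMNS = ["onset", "duration", "trial_type", "response_time", "response"]

SCALP, EOG, ECG = "scalp", "eog", "ecg"


class FormatError(RuntimeError):
    """A file is missing, inconsistent, or not in the advertised format."""


class UnitError(FormatError):
    """Channel units could not be mapped to microvolts."""


class ValidationError(ValueError):
    """A domain invariant (e.g. monotone onsets) is violated."""


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    sfreq : float
        Sampling frequency in Hz.
    channel_labels : list of str
    channel_kinds : list of str
        One of ``{"scalp", "eog", "ecg"}`` per channel.
    triggers : list of (int, str)
        ``(sample_index, code)`` pairs, 0-based samples.
    """

    data: np.ndarray
    sfreq: float
    channel_labels: list
    channel_kinds: list
    triggers: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be channels x samples")
        if self.sfreq <= 0:
            raise ValidationError("sfreq must be positive")
        n_ch, n_s = self.data.shape
        if len(self.channel_labels) != n_ch or len(self.channel_kinds) != n_ch:
            raise ValidationError("labels/kinds must match channel count")
        for s, _code in self.triggers:
            if not (0 <= s < n_s):
                raise ValidationError(f"trigger sample {s} outside [0, {n_s})")

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[1]

    @property
    def duration_s(self):
        return self.n_samples / self.sfreq

    def trigger_samples(self, code=None):
        """Sample indices of triggers, optionally filtered by code."""
        return np.array(
            [s for s, c in self.triggers if code is None or c == code], dtype=int
        )

    def channels_of_kind(self, kind):
        return [i for i, k in enumerate(self.channel_kinds) if k == kind]


def infer_channel_kinds(labels, overrides=None):
    """Infer scalp/EOG/ECG channel kinds from label strings.

    Labels matching ``/ECG/i`` become ECG, ``/EOG/i`` EOG, everything else
    scalp.  ``overrides`` maps label -> kind and wins over inference.
    """
    overrides = overrides or {}
    kinds = []
    for lab in labels:
        if lab in overrides:
            kinds.append(overrides[lab])
        elif re.search("ecg", lab, re.IGNORECASE):
            kinds.append(ECG)
        elif re.search("eog", lab, re.IGNORECASE):
            kinds.append(EOG)
        else:
            kinds.append(SCALP)
    return kinds


def read_recording(path, dialect=None, kind_overrides=None):
    """Read an EEG file into a :class:`Recording`.

    Parameters
    ----------
    path : str or Path
        ``.vhdr`` (BrainVision) or ``.edf`` file.
    dialect : {"brainvision", "edf"}, optional
        Inferred from the extension when omitted.
    kind_overrides : dict, optional
        label -> kind map overriding name-based channel-kind inference.
    """
    import mne

    path = Path(path)
    if dialect is None:
        dialect = {"vhdr": "brainvision", "edf": "edf"}.get(
            path.suffix.lstrip(".").lower()
        )
    if dialect == "brainvision":
        for ext in (".vmrk", ".eeg"):
            if not path.with_suffix(ext).exists():
                raise FormatError(f"missing companion file {path.with_suffix(ext)}")
        try:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise FormatError(f"cannot parse {path}: {exc}") from exc
    elif dialect == "edf":
        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot parse {path}: {exc}") from exc
    else:
        raise FormatError(f"unknown EEG dialect for {path}")

    data = raw.get_data() * 1e6  # mne uses volts internally
    labels = list(raw.ch_names)
    triggers = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        code = desc.split("/")[-1]
        if code.lower().startswith("new segment"):
            continue
        triggers.append((int(round(onset * raw.info["sfreq"])), code))
    return Recording(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        channel_labels=labels,
        channel_kinds=infer_channel_kinds(labels, kind_overrides),
        triggers=triggers,
    )


def write_brainvision(rec, vhdr_path):
    """Write a Recording as a BrainVision triplet (IEEE float32, multiplexed).

    Minimal writer used for fixtures and caches; readable by standard
    BrainVision parsers.
    """
    vhdr_path = Path(vhdr_path)
    stem = vhdr_path.stem
    eeg_path = vhdr_path.with_suffix(".eeg")
    vmrk_path = vhdr_path.with_suffix(".vmrk")
    sampling_interval_us = 1e6 / rec.sfreq

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels):
        lines.append(f"Ch{i + 1}={lab},,1,µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (sample, code) in enumerate(rec.triggers, start=2):
        # marker positions are 1-based in BrainVision
        mlines.append(f"Mk{k}=Stimulus,{code},{sample + 1},1,0")
    vmrk_path.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg_path)
    return vhdr_path


def write_edf(rec, path):
    """Write a Recording as a minimal EDF file (16-bit, 1 s records).

    The duration is truncated to whole seconds and EDF carries no trigger
    channel here; events travel in the events TSV.  Quantization to 16 bits
    limits round-trip accuracy to ~1e-4 of the full scale.
    """
    path = Path(path)
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1 s record
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise FormatError("recording shorter than one EDF record")
    ns = rec.n_channels
    data = rec.data[:, : n_rec * spr]

    pmin = float(min(data.min(), -1.0))
    pmax = float(max(data.max(), 1.0))
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.round((data - pmin) * scale + dmin).astype("<i2")

    def f(x, w):
        s = str(x)[:w]
        return s.ljust(w).encode("ascii")

    hdr = b"".join([
        f("0", 8), f("synthetic", 80), f("eegfmri", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(256 * (ns + 1), 8), f("", 44), f(n_rec, 8), f(1, 8), f(ns, 4),
    ])
    sig = b"".join([
        b"".join(f(lab[:16], 16) for lab in rec.channel_labels),
        b"".join(f("", 80) for _ in range(ns)),
        b"".join(f("uV", 8) for _ in range(ns)),
        b"".join(f(round(pmin, 2), 8) for _ in range(ns)),
        b"".join(f(round(pmax, 2), 8) for _ in range(ns)),
        b"".join(f(dmin, 8) for _ in range(ns)),
        b"".join(f(dmax, 8) for _ in range(ns)),
        b"".join(f("", 80) for _ in range(ns)),
        b"".join(f(spr, 8) for _ in range(ns)),
        b"".join(f("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            block = dig[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # signal-by-signal within record
    return path


# ---------------------------------------------------------------------------
# EventTable
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Per-trial onsets, types, responses and RTs.

    ``table`` columns: onset (s), duration (s), trial_type ({Go, Nogo}),
    response_time (s, NaN when no press), response
    ({correct, omission, commission}).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in EVENT_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"missing event columns: {missing}")
        onsets = t["onset"].to_numpy(float)
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValidationError("event onsets must be strictly increasing")
        bad = ~t["trial_type"].isin(["Go", "Nogo"])
        if bad.any():
            raise ValidationError(f"unknown trial types: {set(t.loc[bad, 'trial_type'])}")
        # a press (finite RT) is exactly what defines correct Go / commission
        pressed = np.isfinite(t["response_time"].to_numpy(float))
        expect = np.where(
            t["trial_type"] == "Go",
            np.where(pressed, "correct", "omission"),
            np.where(pressed, "commission", "correct"),
        )
        if not (t["response"].to_numpy() == expect).all():
            raise ValidationError("response labels inconsistent with trial_type/RT")

    def __len__(self):
        return len(self.table)

    @property
    def onsets(self):
        return self.table["onset"].to_numpy(float)

    @property
    def accuracy(self):
        """1 where the response was correct, else 0 (derived column)."""
        return (self.table["response"] == "correct").astype(int).to_numpy()

    def condition(self):
        """Per-trial condition label in {go_correct, nogo_correct, omission, commission}."""
        t = self.table
        out = np.where(
            t["response"] == "correct",
            np.where(t["trial_type"] == "Go", "go_correct", "nogo_correct"),
            t["response"],
        )
        return np.asarray(out, dtype=object)


def classify_response(trial_type, pressed):
    """Response label from trial type and whether a button press occurred."""
    if trial_type == "Go":
        return "correct" if pressed else "omission"
    return "commission" if pressed else "correct"


def read_events(path):
    df = pd.read_csv(path, sep="\t")
    if "response" not in df.columns:
        pressed = np.isfinite(df["response_time"].to_numpy(float))
        df["response"] = [
            classify_response(tt, p) for tt, p in zip(df["trial_type"], pressed)
        ]
    if "duration" not in df.columns:
        df["duration"] = 0.0
    return EventTable(df[EVENT_COLUMNS].copy())


def write_events(events, path):
    events.table[EVENT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="n/a")
    return Path(path)


# ---------------------------------------------------------------------------
# VolumeSeries (NIfTI)
# ---------------------------------------------------------------------------

@dataclass
class VolumeSeries:
    """4D BOLD series with repetition time and equilibration discard count."""

    data: np.ndarray
    tr_s: float
    affine: np.ndarray = None
    n_discard: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] < 1:
            raise ValidationError("volume series must be 4D with t >= 1")
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be positive")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_volumes(self):
        return self.data.shape[3]

    def analyzed(self):
        """Data after discarding the leading equilibration volumes."""
        return self.data[..., self.n_discard:]

    def scan_times(self):
        """Acquisition times of the analyzed volumes on the run clock (s).

        t = 0 at the first analyzed volume.
        """
        n = self.n_volumes - self.n_discard
        return np.arange(n) * self.tr_s


def read_volumes(path, n_discard=0):
    import nibabel as nib

    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"expected a 4D NIfTI, got {img.ndim}D")
    tr = float(img.header.get_zooms()[3])
    return VolumeSeries(
        data=np.asanyarray(img.dataobj, dtype=float),
        tr_s=tr,
        affine=img.affine,
        n_discard=n_discard,
    )


def write_volumes(series, path):
    import nibabel as nib

    img = nib.Nifti1Image(series.data, series.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = series.tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# HDF5 run container
# ---------------------------------------------------------------------------

def save_recording_h5(rec, path, group="recording"):
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("data", data=rec.data)
        g.attrs["sfreq"] = rec.sfreq
        g.create_dataset("labels", data=np.array(rec.channel_labels, dtype="S"))
        g.create_dataset("kinds", data=np.array(rec.channel_kinds, dtype="S"))
        g.create_dataset(
            "trigger_samples", data=np.array([s for s, _ in rec.triggers], dtype=int)
        )
        g.create_dataset(
            "trigger_codes",
            data=np.array([c for _, c in rec.triggers], dtype="S"),
        )
    return Path(path)


def load_recording_h5(path, group="recording"):
    with h5py.File(path, "r") as fh:
        g = fh[group]
        return Recording(
            data=g["data"][()],
            sfreq=float(g.attrs["sfreq"]),
            channel_labels=[s.decode() for s in g["labels"][()]],
            channel_kinds=[s.decode() for s in g["kinds"][()]],
            triggers=list(
                zip(
                    (int(s) for s in g["trigger_samples"][()]),
                    (c.decode() for c in g["trigger_codes"][()]),
                )
            ),
        )


def save_decomposition_h5(dec, path, group="decomposition"):
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("unmixing", data=dec.unmixing)
        g.create_dataset("mixing", data=dec.mixing)
        g.create_dataset(
            "flag_ics", data=np.array(sorted(dec.artifact_flags), dtype=int)
        )
        g.create_dataset(
            "flag_reasons",
            data=np.array(
                [dec.artifact_flags[i] for i in sorted(dec.artifact_flags)], dtype="S"
            ),
        )
        g.attrs["metadata"] = json.dumps(dec.metadata)
    return Path(path)


def load_decomposition_h5(path, group="decomposition"):
    from .preprocess import Decomposition

    with h5py.File(path, "r") as fh:
        g = fh[group]
        flags = {
            int(i): r.decode()
            for i, r in zip(g["flag_ics"][()], g["flag_reasons"][()])
        }
        return Decomposition(
            unmixing=g["unmixing"][()],
            mixing=g["mixing"][()],
            artifact_flags=flags,
            metadata=json.loads(g.attrs["metadata"]),
        )


def crosscheck_triggers(rec, events, code_map, tol_s=0.01):
    """Compare EEG stimulus trigger times against the events table.

    ``code_map`` maps trigger codes to trial types (e.g. {"S  1": "Go"}).
    Mismatches are logged, never fatal: the events table wins.
    Returns the number of mismatching trials.
    """
    stim = [(s, code_map[c]) for s, c in rec.triggers if c in code_map]
    n_bad = 0
    if len(stim) != len(events):
        logger.warning(
            "trigger/event count mismatch: %d triggers vs %d events",
            len(stim), len(events),
        )
        n_bad += abs(len(stim) - len(events))
    for (sample, ttype), (_, row) in zip(stim, events.table.iterrows()):
        if ttype != row["trial_type"] or abs(sample / rec.sfreq - row["onset"]) > tol_s:
            n_bad += 1
    if n_bad:
        logger.warning("%d trials mismatch between EEG triggers and events", n_bad)
    return n_bad
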