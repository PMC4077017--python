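"""Shared fixtures: one scaled synthetic run analyzed end to end.

The scaled configuration keeps the trial structure that calibrates the
Z = 0.275 threshold (300 trials, 29% Nogo -> ~87 Nogo epochs) but uses 16
channels and a 141-volume run so the per-test ICA stays cheap.
"""

import numpy as np
import pytest

from eegfmri.features import median_rt
from eegfmri.icselect import AnalysisWindows, epoch_units, select_nogo_ics, select_visual_ics
from eegfmri.preprocess import detect_artifact_events, fit_unmixing, flag_artifact_ics
from eegfmri.synth import SimConfig, gen_bold, gen_eeg, gen_paradigm


def scaled_config(seed, **overrides):
    base = dict(n_channels=16, n_trials=300, n_volumes=141, n_discard=5)
    base.update(overrides)
    return SimConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def sim_run():
    """One synthetic run: (config, events, recording, truth, bold)."""
    cfg = scaled_config(seed=11)
    events = gen_paradigm(cfg)
    rec, truth = gen_eeg(events, cfg)
    bold = gen_bold(events, truth, cfg)
    return cfg, events, rec, truth, bold


@pytest.fixture(scope="session")
def decomposition(sim_run):
    """Fitted ICA with BCG/blink artifact flags for the shared run."""
    cfg, events, rec, truth, bold = sim_run
    dec = fit_unmixing(rec, seed=cfg.seed)
    for kind, reason in (("ecg", "bcg"), ("eog", "blink")):
        times = detect_artifact_events(rec, kind)
        flag_artifact_ics(dec, rec, times, reason, seed=cfg.seed + 1)
    return dec


@pytest.fixture(scope="session")
def ic_epochs(sim_run, decomposition):
    cfg, events, rec, truth, bold = sim_run
    acts = decomposition.activations(rec.data)
    return epoch_units(acts, rec.sfreq, events)


@pytest.fixture(scope="session")
def selections(sim_run, decomposition, ic_epochs):
    cfg, events, rec, truth, bold = sim_run
    windows = AnalysisWindows.from_median_rt(median_rt(events))
    nogo = select_nogo_ics(ic_epochs, windows,
                           exclude_ics=decomposition.artifact_flags)
    visual = select_visual_ics(ic_epochs, windows,
                               exclude_ics=decomposition.artifact_flags)
    return windows, nogo, visual


def best_matching_ic(dec, topography):
    """IC whose (unit-norm) mixing column best matches a planted topography."""
    cols = dec.mixing / np.linalg.norm(dec.mixing, axis=0)
    cos = np.abs(cols.T @ topography)
    return int(np.argmax(cos)), float(cos.max())
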