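"""In-memory containers shared across the pipeline: recordings and epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: 64-channel actiCAP-style 10-10 montage (FCz recovered after re-referencing)
MONTAGE_64 = (
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
)

#: reduced montage carrying every channel the analyses touch; used for
#: desk-scale cohort simulations
MONTAGE_16 = (
    "F1", "F2", "Fz", "FC1", "FC2", "FCz",
    "Cz", "CPz", "Pz", "POz", "Oz", "O1", "O2",
    "AFz", "TP9", "TP10",
)

MIDFRONTAL_ELECTRODES = ("F1", "F2", "Fz", "FC1", "FC2", "FCz")
MIDLINE_ELECTRODES = ("Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz")
MASTOIDS = ("TP9", "TP10")


def montage_positions(ch_names=MONTAGE_64) -> np.ndarray:
    """Unit-sphere electrode positions for the given 10-10 channel names."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    out = np.empty((len(ch_names), 3))
    for i, name in enumerate(ch_names):
        if name not in pos:
            raise KeyError(f"channel {name!r} not in the standard 10-05 montage")
        v = np.asarray(pos[name], dtype=float)
        out[i] = v / np.linalg.norm(v)
    return out


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with stimulus events.

    data is channels x samples in microvolts; events is an (n_events, 2) int
    array of (sample_index, marker); markers are 1-based trial indices.
    """

    ch_names: tuple[str, ...]
    positions: np.ndarray  # (n_ch, 3) unit sphere
    fs: float
    data: np.ndarray  # (n_ch, n_samples) float32, microvolts
    events: np.ndarray  # (n_events, 2) int

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("data rows must match channel labels")
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if self.events.size and (
            self.events[:, 0].min() < 0 or self.events[:, 0].max() >= self.data.shape[1]
        ):
            raise ValueError("event samples outside the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick(self, names) -> "EEGRecording":
        idx = [self.ch_names.index(n) for n in names]
        return replace(
            self,
            ch_names=tuple(names),
            positions=self.positions[idx],
            data=self.data[idx],
        )

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), events=self.events.copy())


@dataclass
class Epochs:
    """Stimulus-locked epochs: trials x channels x samples.

    `info` carries one row per retained epoch (trial index, condition, rt_ms,
    correct) aligned with the first axis of `data`.
    """

    data: np.ndarray  # (n_epochs, n_ch, n_times) microvolts
    times: np.ndarray  # seconds relative to stimulus onset
    fs: float
    ch_names: tuple[str, ...]
    info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-dimensional")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]
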