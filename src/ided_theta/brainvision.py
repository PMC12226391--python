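"""BrainVision (.vhdr/.vmrk/.eeg) writing and reading.

Writing emits IEEE float32 multiplexed data with "S  <n>"-style stimulus
markers, the layout produced by BrainVision Recorder.  Reading goes through
MNE's BrainVision reader so round-trips are validated against the field's
standard parser.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import EEGRecording, montage_positions

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Synthetic recording written by ided-theta

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
; Data orientation: MULTIPLEXED=ch1,pt1, ch2,pt1 ...
DataOrientation=MULTIPLEXED
NumberOfChannels={n_ch}
; Sampling interval in microseconds
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Each entry: Ch<Channel number>=<Name>,<Reference channel name>,
; <Resolution in "Unit">,<Unit>
{channels}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
; Each entry: Mk<Marker number>=<Type>,<Description>,<Position in data points>,
; <Size in data points>, <Channel number (0 = marker is related to all channels)>
Mk1=New Segment,,1,1,0,00000000000000000000
{markers}
"""


def write_brainvision(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a BrainVision triplet; `path` names the .vhdr."""
    path = Path(path)
    if path.suffix != ".vhdr":
        path = path.with_suffix(".vhdr")
    stem = path.stem
    channels = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.ch_names)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem,
        n_ch=len(rec.ch_names),
        sampling_interval=int(round(1e6 / rec.fs)),
        channels=channels,
    )
    markers = "\n".join(
        f"Mk{i + 2}=Stimulus,S{int(marker):>3d},{int(sample) + 1},1,0"
        for i, (sample, marker) in enumerate(rec.events)
    )
    vmrk = _VMRK_TEMPLATE.format(stem=stem, markers=markers)
    path.write_text(vhdr, encoding="utf-8")
    path.with_suffix(".vmrk").write_text(vmrk, encoding="utf-8")
    rec.data.astype("<f4").T.tofile(path.with_suffix(".eeg"))
    return path


def read_brainvision(path: str | Path) -> EEGRecording:
    """Read a BrainVision triplet (via MNE) into an EEGRecording."""
    import mne

    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data = (raw.get_data() * 1e6).astype(np.float32)  # volts -> microvolts
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    stim = []
    code_to_marker = {}
    for desc, code in event_id.items():
        if desc.startswith("Stimulus/S"):
            code_to_marker[code] = int(desc.split("S")[-1])
    for sample, _, code in events:
        if code in code_to_marker:
            stim.append((int(sample), code_to_marker[code]))
    ch_names = tuple(raw.ch_names)
    return EEGRecording(
        ch_names=ch_names,
        positions=montage_positions(ch_names),
        fs=float(raw.info["sfreq"]),
        data=data,
        events=np.array(stim, dtype=np.int64).reshape(-1, 2),
    )
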