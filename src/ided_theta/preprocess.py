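"""Continuous-data conditioning: re-referencing, filtering, semi-automatic
artifact detection, spherical-spline channel interpolation, downsampling and
stimulus-locked epoching.

The artifact rules mirror BrainVision-Analyzer-style semi-automatic criteria:
a gradient rule (maximum sample-to-sample voltage step), a max-difference
rule (peak-to-peak within a 200 ms sliding interval), and a low-activity
rule (peak-to-peak below a floor within 100 ms).  Each violation marks a
guard window around the event; channels with more than 20 % marked samples
are replaced by spherical-spline interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.signal
from numpy.polynomial import legendre
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .data import MASTOIDS, EEGRecording, Epochs


class PreprocessError(RuntimeError):
    pass


@dataclass(frozen=True)
class ArtifactCriteria:
    """Thresholds of the three artifact rules (all in microvolts / ms)."""

    max_voltage_step: float = 50.0
    step_mark_window: float = 400.0
    max_abs_difference: float = 600.0
    diff_interval: float = 200.0
    diff_mark_window: float = 1000.0
    min_activity: float = 0.5
    low_interval: float = 100.0
    low_mark_window: float = 200.0

    def __post_init__(self) -> None:
        vals = (self.max_voltage_step, self.step_mark_window, self.max_abs_difference,
                self.diff_interval, self.diff_mark_window, self.min_activity,
                self.low_interval, self.low_mark_window)
        if any(v <= 0 for v in vals):
            raise ValueError("all artifact criteria must be positive")

    def second_pass(self) -> "ArtifactCriteria":
        """Stricter re-run after the ocular-correction hook (max-diff 400 uV)."""
        return replace(self, max_abs_difference=400.0)


@dataclass
class ArtifactMask:
    """Per-channel boolean bad-sample mask plus rejected fractions."""

    mask: np.ndarray  # (n_ch, n_samples) bool
    rejected_fraction: np.ndarray  # (n_ch,)

    def combine(self, other: "ArtifactMask") -> "ArtifactMask":
        m = self.mask | other.mask
        return ArtifactMask(mask=m, rejected_fraction=m.mean(axis=1))


def rereference_linked_mastoids(rec: EEGRecording) -> EEGRecording:
    """Subtract the TP9/TP10 average (virtually linked mastoids) everywhere."""
    missing = [m for m in MASTOIDS if m not in rec.ch_names]
    if missing:
        raise PreprocessError(f"mastoid channels missing: {missing}")
    idx = [rec.ch_names.index(m) for m in MASTOIDS]
    ref = rec.data[idx].mean(axis=0, dtype=np.float64).astype(np.float32)
    out = rec.copy()
    out.data -= ref[None, :]
    return out


def bandpass(rec: EEGRecording, low_hz: float = 1.0, high_hz: float = 100.0,
             order: int = 2) -> EEGRecording:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise PreprocessError("band edges must satisfy 0 < low < high < fs/2")
    sos = scipy.signal.butter(order, [low_hz, high_hz], btype="bandpass",
                              fs=rec.fs, output="sos")
    out = rec.copy()
    out.data = scipy.signal.sosfiltfilt(sos, rec.data, axis=1).astype(np.float32)
    return out


def _mark(flags: np.ndarray, half_window: int) -> np.ndarray:
    """Dilate boolean flags by +-half_window samples."""
    if not flags.any():
        return flags
    return maximum_filter1d(flags.astype(np.uint8), size=2 * half_window + 1,
                            axis=-1).astype(bool)


def detect_artifacts(rec: EEGRecording,
                     criteria: ArtifactCriteria | None = None) -> ArtifactMask:
    """Apply the gradient, max-difference and low-activity rules per channel.

    Sliding intervals advance sample by sample; each rule marks a guard
    window around the violation and the three masks are OR-combined.
    """
    criteria = criteria or ArtifactCriteria()
    fs = rec.fs
    x = rec.data
    n_ch, n = x.shape
    ms = fs / 1000.0

    mask = np.zeros((n_ch, n), dtype=bool)

    # gradient rule: absolute sample-to-sample difference at the native rate
    step = np.abs(np.diff(x, axis=1)) > criteria.max_voltage_step
    g = np.zeros_like(mask)
    g[:, 1:] = step
    mask |= _mark(g, int(round(criteria.step_mark_window * ms)))

    # max-difference rule: peak-to-peak within a sliding interval
    w = max(int(round(criteria.diff_interval * ms)), 2)
    ptp = maximum_filter1d(x, size=w, axis=1) - minimum_filter1d(x, size=w, axis=1)
    mask |= _mark(ptp > criteria.max_abs_difference,
                  int(round(criteria.diff_mark_window * ms)))

    # low-activity rule: peak-to-peak below the floor within a sliding interval
    w = max(int(round(criteria.low_interval * ms)), 2)
    ptp = maximum_filter1d(x, size=w, axis=1) - minimum_filter1d(x, size=w, axis=1)
    mask |= _mark(ptp < criteria.min_activity,
                  int(round(criteria.low_mark_window * ms)))

    return ArtifactMask(mask=mask, rejected_fraction=mask.mean(axis=1))


def spherical_spline_matrix(good_pos: np.ndarray, bad_pos: np.ndarray,
                            order: int = 2, degree: int = 10,
                            lam: float = 1e-5) -> np.ndarray:
    """Perrin-style spherical-spline interpolation operator.

    Returns a (n_bad, n_good) matrix mapping good-channel values to estimates
    at the bad sites; `order` is the spline order m, `degree` the number of
    Legendre terms, `lam` the ridge regularization added to the diagonal.
    """
    n = np.arange(1, degree + 1)
    gcoef = (2 * n + 1) / (n**order * (n + 1) ** order) / (4 * np.pi)

    def gfun(cosang: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], gcoef])
        return legendre.legval(np.clip(cosang, -1, 1), c)

    G = gfun(good_pos @ good_pos.T) + lam * np.eye(len(good_pos))
    Gb = gfun(bad_pos @ good_pos.T)
    # solve with the zero-sum constraint on the spline coefficients
    m = len(good_pos)
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = G
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    Ainv = np.linalg.pinv(A)
    # interpolated value: [Gb 1] @ Ainv @ [y; 0]
    B = np.hstack([Gb, np.ones((len(bad_pos), 1))])
    return B @ Ainv[:, :m]


def interpolate_bad_channels(rec: EEGRecording, mask: ArtifactMask,
                             threshold: float = 0.20, order: int = 2,
                             degree: int = 10, lam: float = 1e-5,
                             ) -> tuple[EEGRecording, list[str]]:
    """Replace channels with > `threshold` rejected samples by spherical-spline
    estimates from the remaining channels.  Refuses if more than 25 % of
    channels are bad."""
    bad = np.flatnonzero(mask.rejected_fraction > threshold)
    if len(bad) == 0:
        return rec, []
    if len(bad) > 0.25 * len(rec.ch_names):
        raise PreprocessError(
            f"{len(bad)} of {len(rec.ch_names)} channels exceed the rejection "
            "threshold; recording quality insufficient for interpolation")
    good = np.setdiff1d(np.arange(len(rec.ch_names)), bad)
    W = spherical_spline_matrix(rec.positions[good], rec.positions[bad],
                                order=order, degree=degree, lam=lam)
    out = rec.copy()
    out.data[bad] = (W @ rec.data[good]).astype(np.float32)
    return out, [rec.ch_names[i] for i in bad]


def downsample(rec: EEGRecording, target_fs: float = 500.0) -> EEGRecording:
    """Anti-aliased decimation to `target_fs`; event indices rescaled."""
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise PreprocessError("target_fs must divide the sampling rate")
    if q == 1:
        return rec.copy()
    out = rec.copy()
    out.data = scipy.signal.decimate(rec.data, q, ftype="fir",
                                     zero_phase=True).astype(np.float32)
    out.fs = target_fs
    out.events = rec.events.copy()
    out.events[:, 0] = np.round(rec.events[:, 0] / q).astype(np.int64)
    return out


def epoch(rec: EEGRecording, behaviour: pd.DataFrame, tmin: float = -1.250,
          tmax: float = 3.000, reject_with: ArtifactMask | None = None,
          analysis_channels: tuple[str, ...] | None = None,
          conditions=("repeat", "ID", "ED"), correct_only: bool = True,
          dc_window: tuple[float, float] = (-0.250, 0.0)) -> Epochs:
    """Extract stimulus-locked analysis epochs.

    Keeps trials of the requested conditions followed by correct responses;
    drops epochs overlapping masked samples on the analysis channels.  The
    mean of `dc_window` is subtracted per channel (DC step only; power ratios
    are unaffected).  The sample at `tmax` is included when it falls exactly
    on the grid (half-open convention otherwise).
    """
    fs = rec.fs
    i0 = int(round(tmin * fs))
    i1 = int(np.floor(tmax * fs + 1e-9))
    times = np.arange(i0, i1 + 1) / fs
    behaviour = behaviour.set_index("trial", drop=False)

    ch_idx = None
    if reject_with is not None and analysis_channels is not None:
        ch_idx = [rec.ch_names.index(c) for c in analysis_channels]

    rows, arrays = [], []
    for sample, marker in rec.events:
        trial = int(marker) - 1
        if trial not in behaviour.index:
            continue
        b = behaviour.loc[trial]
        if b["condition"] not in conditions:
            continue
        if correct_only and not bool(b["correct"]):
            continue
        lo, hi = sample + i0, sample + i1
        if lo < 0 or hi >= rec.n_samples:
            raise PreprocessError(f"epoch for trial {trial} outside the recording")
        if reject_with is not None:
            sub = reject_with.mask[ch_idx] if ch_idx is not None else reject_with.mask
            if sub[:, lo : hi + 1].any():
                continue
        arrays.append(rec.data[:, lo : hi + 1])
        rows.append({"trial": trial, "condition": b["condition"],
                     "rt_ms": b["rt_ms"], "correct": bool(b["correct"])})
    if not arrays:
        raise PreprocessError("no surviving epochs")
    data = np.stack(arrays).astype(np.float32)
    dsel = (times >= dc_window[0] - 1e-9) & (times <= dc_window[1] + 1e-9)
    data -= data[:, :, dsel].mean(axis=2, keepdims=True)
    return Epochs(data=data, times=times, fs=fs, ch_names=rec.ch_names,
                  info=pd.DataFrame(rows))


def preprocess_recording(rec: EEGRecording, behaviour: pd.DataFrame,
                         criteria: ArtifactCriteria | None = None,
                         target_fs: float = 500.0,
                         analysis_channels: tuple[str, ...] | None = None,
                         ocular_hook=None) -> tuple[Epochs, dict]:
    """Full conditioning chain: re-reference, band-pass, two artifact passes
    (around the ocular-correction hook), interpolation, downsampling,
    epoching.  Returns analysis epochs and a JSON-serializable report."""
    criteria = criteria or ArtifactCriteria()
    rec = rereference_linked_mastoids(rec)
    rec = bandpass(rec)
    if ocular_hook is None:
        # without the hook the stricter second pass subsumes the first
        mask = detect_artifacts(rec, criteria.second_pass())
    else:
        mask1 = detect_artifacts(rec, criteria)
        rec = ocular_hook(rec)
        mask = mask1.combine(detect_artifacts(rec, criteria.second_pass()))
    rec, interpolated = interpolate_bad_channels(rec, mask)
    q = int(round(rec.fs / target_fs))
    rec = downsample(rec, target_fs)
    ds_mask = ArtifactMask(
        mask=mask.mask[:, ::q][:, : rec.n_samples],
        rejected_fraction=mask.rejected_fraction,
    )
    epochs = epoch(rec, behaviour, reject_with=ds_mask,
                   analysis_channels=analysis_channels)
    report = {
        "rejected_fraction": {c: float(f) for c, f in
                              zip(rec.ch_names, mask.rejected_fraction)},
        "interpolated": interpolated,
        "n_epochs": int(epochs.n_epochs),
    }
    return epochs, report
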