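"""Morlet wavelet time-frequency analysis and midfrontal theta extraction.

Power is computed by convolution with unit-energy complex Morlet wavelets
(7 cycles, support truncated at 3 SD of the Gaussian envelope), sampled on a
50 ms output grid.  Condition-level summaries follow the event-related
spectral perturbation convention: power is averaged across trials first and
then expressed in dB relative to a pre-stimulus baseline computed from the
common average of all of a participant's included trials,

    activity_dB = 10 * log10(activity / baseline),

per channel and frequency bin.  Single-trial theta is measured on the linear
power scale with the common baseline subtracted (no log), which keeps the
estimate unbiased under additive background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .data import MIDFRONTAL_ELECTRODES, MIDLINE_ELECTRODES, Epochs

THETA_BAND = (4.0, 8.0)
THETA_WINDOW = (0.250, 0.500)
BASELINE_WINDOW = (-0.400, -0.200)
DEFAULT_FREQS = np.arange(1.0, 61.0)
TIME_STEP = 0.050

N_CYCLES = 7.0
SD_TRUNCATE = 3.0


@dataclass
class TFR:
    """Time-frequency power: rows x channels x frequencies x times.

    Rows are trials for single-trial transforms or conditions after trial
    averaging; `info` has one entry per row.  `valid` flags (freq, time) cells
    whose full wavelet support lies inside the epoch; invalid cells are NaN.
    """

    power: np.ndarray  # (n_rows, n_ch, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    ch_names: tuple[str, ...]
    valid: np.ndarray  # (n_freqs, n_times) bool
    units: str = "raw"  # "raw" | "dB"
    info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("frequency and time grids must be strictly increasing")

    def channel_index(self, names) -> list[int]:
        missing = [n for n in names if n not in self.ch_names]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return [self.ch_names.index(n) for n in names]


def morlet_wavelet(freq: float, fs: float, n_cycles: float = N_CYCLES,
                   sd_truncate: float = SD_TRUNCATE) -> np.ndarray:
    """Unit-energy complex Morlet wavelet sampled at fs.

    The Gaussian envelope has sigma_t = n_cycles / (2*pi*freq); support is
    truncated at +-sd_truncate * sigma_t.  Discrete energy sum |w|^2 * dt = 1.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.floor(sd_truncate * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / fs)
    return w


def wavelet_support(freq: float, n_cycles: float = N_CYCLES,
                    sd_truncate: float = SD_TRUNCATE) -> float:
    """Half-length (seconds) of the truncated wavelet at `freq`."""
    return sd_truncate * n_cycles / (2.0 * np.pi * freq)


def output_grid(times: np.ndarray, step: float = TIME_STEP) -> np.ndarray:
    """Indices into `times` hitting the step grid (multiples of `step`)."""
    k0 = int(np.ceil(round(times[0] / step, 9)))
    k1 = int(np.floor(round(times[-1] / step, 9)))
    grid = np.arange(k0, k1 + 1) * step
    idx = np.searchsorted(times, grid - 0.5 / 1e9)
    idx = np.clip(idx, 0, len(times) - 1)
    # snap to nearest sample
    for j, g in enumerate(grid):
        if idx[j] + 1 < len(times) and abs(times[idx[j] + 1] - g) < abs(times[idx[j]] - g):
            idx[j] += 1
    return idx


def _auto_decimation(fs: float, fmax: float, step: float) -> int:
    """Largest decimation factor keeping >= 4x oversampling of fmax and an
    integer number of samples per output step."""
    best = 1
    for q in range(2, 26):
        new_fs = fs / q
        if new_fs < 4.0 * fmax:
            continue
        if abs(new_fs * step - round(new_fs * step)) > 1e-9:
            continue
        best = q
    return best


def morlet_power(epochs: Epochs, freqs=None, n_cycles: float = N_CYCLES,
                 step: float = TIME_STEP, auto_decimate: bool = True) -> TFR:
    """Raw wavelet power of stimulus-locked epochs on the 50 ms grid.

    Grid cells whose wavelet support extends past the epoch edges are flagged
    invalid and set to NaN rather than zero-filled.  When the requested
    frequencies sit far below Nyquist the signal is decimated internally
    (anti-aliased polyphase FIR) before convolution; the output grid is
    unchanged and the passband response in the analysis bands is flat.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    fs = epochs.fs
    if auto_decimate:
        q = _auto_decimation(fs, float(freqs.max()), step)
        if q > 1:
            data = scipy.signal.resample_poly(
                epochs.data.astype(np.float64), 1, q, axis=2
            ).astype(np.float32)
            epochs = Epochs(data=data, times=epochs.times[::q], fs=fs / q,
                            ch_names=epochs.ch_names, info=epochs.info)
            fs = epochs.fs
    n_ep, n_ch, n_t = epochs.data.shape
    grid_idx = output_grid(epochs.times, step)
    out_times = epochs.times[grid_idx]

    max_half = int(np.floor(SD_TRUNCATE * n_cycles / (2 * np.pi * freqs.min()) * fs))
    nfft = scipy.fft.next_fast_len(n_t + 2 * max_half + 1)
    x = epochs.data.reshape(n_ep * n_ch, n_t).astype(np.complex64)
    Xc = scipy.fft.fft(x, nfft, axis=-1, workers=1)

    power = np.empty((n_ep, n_ch, len(freqs), len(grid_idx)), dtype=np.float32)
    valid = np.empty((len(freqs), len(grid_idx)), dtype=bool)
    t0, t1 = epochs.times[0], epochs.times[-1]
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, fs, n_cycles).astype(np.complex64)
        half = (len(w) - 1) // 2
        Wc = scipy.fft.fft(w, nfft)
        y = scipy.fft.ifft(Xc * Wc.astype(np.complex64), axis=-1, workers=1)
        y = y[:, half : half + n_t] / fs
        p = (np.abs(y) ** 2).astype(np.float32)
        power[:, :, fi, :] = p.reshape(n_ep, n_ch, n_t)[:, :, grid_idx]
        h = wavelet_support(f, n_cycles)
        valid[fi] = (out_times >= t0 + h - 1e-9) & (out_times <= t1 - h + 1e-9)
        power[:, :, fi, ~valid[fi]] = np.nan
    return TFR(
        power=power,
        freqs=freqs,
        times=out_times,
        ch_names=epochs.ch_names,
        valid=valid,
        units="raw",
        info=epochs.info.reset_index(drop=True),
    )


def trial_average(tfr: TFR, by: str = "condition") -> TFR:
    """Average raw power across trials within levels of an info column."""
    if tfr.units != "raw":
        raise ValueError("trial averaging operates on raw power")
    levels = [lv for lv in ("repeat", "ID", "ED") if lv in set(tfr.info[by])]
    levels += sorted(set(tfr.info[by]) - set(levels))
    rows = []
    for lv in levels:
        sel = np.flatnonzero((tfr.info[by] == lv).to_numpy())
        rows.append(tfr.power[sel].mean(axis=0))
    return replace(
        tfr,
        power=np.stack(rows),
        info=pd.DataFrame({by: levels}),
    )


def compute_baseline(tfr: TFR, window=BASELINE_WINDOW) -> np.ndarray:
    """Common-average baseline power per (channel, frequency).

    The baseline is the mean raw power in `window`, averaged over all of the
    participant's included trials, separately per channel and frequency bin.
    Frequencies whose baseline cells are edge-flagged come out NaN.
    """
    if tfr.units != "raw":
        raise ValueError("baseline must be computed from raw power")
    sel = (tfr.times >= window[0] - 1e-9) & (tfr.times <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError("baseline window outside the time grid")
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        base = np.nanmean(tfr.power[:, :, :, sel], axis=(0, 3))
    ok = tfr.valid[:, sel].all(axis=1)
    base[:, ~ok] = np.nan
    with np.errstate(invalid="ignore"):
        if np.any(base[:, ok] <= 0):
            raise ValueError("zero or negative baseline power")
    return base  # (n_ch, n_freqs)


def db_normalize(tfr: TFR, baseline: np.ndarray | None = None,
                 window=BASELINE_WINDOW, reference: TFR | None = None) -> TFR:
    """Normalize power to dB relative to the common-average baseline.

    `reference` (default: `tfr` itself) supplies the trials over which the
    baseline is averaged; pass the full single-trial transform here when
    normalizing condition averages so the baseline is the participant's common
    average.
    """
    if tfr.units != "raw":
        raise ValueError("tfr is already normalized")
    if baseline is None:
        baseline = compute_baseline(reference if reference is not None else tfr, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(tfr.power / baseline[None, :, :, None])
    return replace(tfr, power=db.astype(np.float32), units="dB")


def _box(tfr: TFR, electrodes, band, window) -> np.ndarray:
    ci = tfr.channel_index(electrodes)
    fsel = (tfr.freqs >= band[0] - 1e-9) & (tfr.freqs <= band[1] + 1e-9)
    tsel = (tfr.times >= window[0] - 1e-9) & (tfr.times <= window[1] + 1e-9)
    if not fsel.any() or not tsel.any():
        raise ValueError("band or window outside the grids")
    if not tfr.valid[np.ix_(fsel, tsel)].all():
        raise ValueError("requested box includes edge-invalid cells")
    box = tfr.power[np.ix_(range(tfr.power.shape[0]), ci, np.flatnonzero(fsel),
                           np.flatnonzero(tsel))]
    return box


def extract_midfrontal_theta(tfr_db: TFR, electrodes=MIDFRONTAL_ELECTRODES,
                             band=THETA_BAND, window=THETA_WINDOW) -> pd.DataFrame:
    """Mean dB over the electrode x frequency x time box, one value per row."""
    box = _box(tfr_db, electrodes, band, window)
    vals = box.mean(axis=(1, 2, 3))
    out = tfr_db.info.copy().reset_index(drop=True)
    out["theta_db"] = vals
    return out


def midline_profile(tfr_db: TFR, electrodes=MIDLINE_ELECTRODES,
                    band=THETA_BAND, window=THETA_WINDOW) -> pd.DataFrame:
    """Per-electrode theta summary along the central midline."""
    frames = []
    for el in electrodes:
        f = extract_midfrontal_theta(tfr_db, electrodes=(el,), band=band, window=window)
        f["electrode"] = el
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def single_trial_theta(tfr_raw: TFR, baseline: np.ndarray | None = None,
                       electrodes=MIDFRONTAL_ELECTRODES, band=THETA_BAND,
                       window=THETA_WINDOW, subtract_baseline: bool = True,
                       per_trial_baseline: bool = False) -> pd.DataFrame:
    """Per-trial midfrontal theta on the linear power scale.

    Default: raw box power minus the participant's common-average baseline
    (subtractive, no log).  `per_trial_baseline` switches to subtracting each
    trial's own baseline-window power instead.
    """
    if tfr_raw.units != "raw":
        raise ValueError("single-trial theta is computed on raw power")
    box = _box(tfr_raw, electrodes, band, window)
    vals = box.mean(axis=(1, 2, 3))
    if subtract_baseline:
        if per_trial_baseline:
            bsel = (tfr_raw.times >= BASELINE_WINDOW[0] - 1e-9) & (
                tfr_raw.times <= BASELINE_WINDOW[1] + 1e-9
            )
            ci = tfr_raw.channel_index(electrodes)
            fsel = (tfr_raw.freqs >= band[0] - 1e-9) & (tfr_raw.freqs <= band[1] + 1e-9)
            b = tfr_raw.power[np.ix_(range(tfr_raw.power.shape[0]), ci,
                                     np.flatnonzero(fsel), np.flatnonzero(bsel))]
            vals = vals - b.mean(axis=(1, 2, 3))
        else:
            if baseline is None:
                baseline = compute_baseline(tfr_raw)
            ci = tfr_raw.channel_index(electrodes)
            fsel = (tfr_raw.freqs >= band[0] - 1e-9) & (tfr_raw.freqs <= band[1] + 1e-9)
            vals = vals - baseline[np.ix_(ci, np.flatnonzero(fsel))].mean()
    out = tfr_raw.info.copy().reset_index(drop=True)
    out["theta_raw"] = vals
    return out
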