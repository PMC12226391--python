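"""Synthetic multichannel EEG and behaviour for the IDED task.

The generator emulates the statistical structure the analysis pipeline
assumes, per age group:

* 1/f background noise, independent across channels, with a configurable
  spectral exponent and band-limited amplitude;
* a stimulus-locked midfrontal theta burst (Hann-windowed ~6 Hz oscillation,
  frontocentral Gaussian topography centred on FCz) whose energy is
  calibrated per condition so the *pipeline-measured* midfrontal dB matches
  the profile's target values;
* an early occipital evoked theta burst (0-200 ms, posterior topography);
* log-normal reaction times with group and condition offsets, calibrated so
  the cohort mean of per-participant median RTs hits the profile target;
* trialwise coupling between burst amplitude and RT imposed through a
  Gaussian copula on their ranks, so the rank correlation the single-trial
  analysis estimates is the profile's `coupling_rho`;
* rare error / no-response trials.

Calibration is a deterministic inversion of the forward model: the expected
wavelet power of the background is computed from the constructed PSD and the
wavelet's spectrum, the burst's wavelet power from a noise-free template, and
the per-condition burst gain solves the closed-form dB equation by
root-finding.  The copula correlation is corrected for the attenuation that
measurement noise induces on rank correlations, estimated once from a seeded
pilot transform of background-only epochs.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.fft
from scipy.optimize import brentq
from scipy.stats import norm

from . import tfr as _tfr
from .data import (
    MIDFRONTAL_ELECTRODES,
    MONTAGE_16,
    MONTAGE_64,
    EEGRecording,
    Epochs,
    montage_positions,
)
from .taskgen import (
    CONDITIONS,
    RESPONSE_DEADLINE_MS,
    TaskConfig,
    TrialSequence,
    generate_sequence,
    score_response,
)

OCCIPITAL_ELECTRODES = ("O1", "Oz", "O2", "POz")
OCCIPITAL_WINDOW = (0.000, 0.200)

#: expected analysis-trial mix (repeat : ID : ED) under the default task plan
CONDITION_TRIAL_WEIGHTS = {"repeat": 0.5, "ID": 0.25, "ED": 0.25}

_ANALYSIS_FS = 500.0


class ProfileError(ValueError):
    """Raised for invalid or unreachable generative configurations."""


@dataclass
class SubjectProfile:
    """Generative parameters of one simulated participant.

    `theta_db` are the target pipeline-measured midfrontal dB elevations per
    condition (250-500 ms, 4-8 Hz, F1/F2/Fz/FC1/FC2/FCz).  `coupling_rho` is
    the target trialwise Spearman correlation between single-trial theta and
    RT.  Filler trials reuse the repeat-condition parameters.
    """

    group: str
    theta_db: dict[str, float]
    rt_mu: dict[str, float]  # natural log of ms
    rt_sigma: dict[str, float]
    coupling_rho: dict[str, float]
    error_rate: dict[str, float]
    occipital_evoked_db: float = 1.5
    noise_exponent: float = 1.0
    noise_uv: float = 10.0  # SD of the 1-100 Hz background, microvolts
    line_noise_uv: float = 0.5
    line_noise_hz: float = 50.0
    amp_sigma: float = 0.5  # log-SD of the per-trial burst amplitude
    burst_freq: float = 6.0
    burst_freq_jitter: float = 0.3
    burst_window: tuple[float, float] = (0.100, 0.650)
    occipital_window: tuple[float, float] = OCCIPITAL_WINDOW
    spatial_sigma: float = 0.6  # radians on the unit sphere
    seed: int = 0

    def __post_init__(self) -> None:
        for c in CONDITIONS:
            for d in (self.theta_db, self.rt_mu, self.rt_sigma, self.coupling_rho,
                      self.error_rate):
                if c not in d:
                    raise ProfileError(f"missing condition {c!r} in profile")
        if any(not 0 <= p <= 1 for p in self.error_rate.values()):
            raise ProfileError("error rates must lie in [0, 1]")
        if any(s <= 0 for s in self.rt_sigma.values()):
            raise ProfileError("rt_sigma must be positive")
        if any(not -1 < r < 1 for r in self.coupling_rho.values()):
            raise ProfileError("coupling_rho must lie in (-1, 1)")
        if any(d < 0 for d in self.theta_db.values()):
            raise ProfileError("theta_db targets must be non-negative")

    def param(self, mapping: dict[str, float], condition: str) -> float:
        return mapping["repeat" if condition == "filler" else condition]


# --------------------------------------------------------------------------
# reaction-time calibration

_RT_COND_OFFSET = {"repeat": 0.0, "ID": 0.115, "ED": 0.235}
_RT_GROUP_OFFSET = {"young": 0.0, "older": 0.33}
_RT_COND_SIGMA = {"repeat": 0.0, "ID": 0.01, "ED": 0.03}
_RT_GROUP_SIGMA = {"young": 0.22, "older": 0.28}

POOLED_MEDIAN_RT_MS = 718.0
ERROR_RATES = {"repeat": 0.010, "ID": 0.020, "ED": 0.027}  # pooled mean 1.90 %


def _mixture_median(mus: np.ndarray, sigmas: np.ndarray, weights: np.ndarray) -> float:
    """Median of a weighted log-normal mixture (analytic CDF + root-find)."""

    def cdf(x: float) -> float:
        return float(np.sum(weights * norm.cdf((np.log(x) - mus) / sigmas)) - 0.5)

    return brentq(cdf, 1.0, 1e6)


@functools.lru_cache(maxsize=None)
def _rt_base(n_young: int = 20, n_older: int = 19,
             target_ms: float = POOLED_MEDIAN_RT_MS) -> float:
    """Base log-RT such that the cohort mean of per-participant medians
    (pooled over repeat/ID/ED with the default trial mix) equals the target."""
    w = np.array([CONDITION_TRIAL_WEIGHTS[c] for c in CONDITIONS])
    medians = {}
    for g in ("young", "older"):
        mus = np.array([_RT_GROUP_OFFSET[g] + _RT_COND_OFFSET[c] for c in CONDITIONS])
        sig = np.array([_RT_GROUP_SIGMA[g] + _RT_COND_SIGMA[c] for c in CONDITIONS])
        medians[g] = _mixture_median(mus, sig, w)
    m0 = (n_young * medians["young"] + n_older * medians["older"]) / (n_young + n_older)
    return float(np.log(target_ms / m0))


def _rt_params(group: str) -> tuple[dict[str, float], dict[str, float]]:
    base = _rt_base()
    mu = {c: base + _RT_GROUP_OFFSET[group] + _RT_COND_OFFSET[c] for c in CONDITIONS}
    sigma = {c: _RT_GROUP_SIGMA[group] + _RT_COND_SIGMA[c] for c in CONDITIONS}
    return mu, sigma


def young_profile(seed: int = 0, **overrides) -> SubjectProfile:
    """Default young-adult profile: graded theta (ED > ID > repeat), positive
    theta-RT coupling, faster RTs."""
    mu, sigma = _rt_params("young")
    params = dict(
        group="young",
        theta_db={"repeat": 1.13, "ID": 1.73, "ED": 2.03},
        rt_mu=mu,
        rt_sigma=sigma,
        coupling_rho={c: float(np.tanh(0.103)) for c in CONDITIONS},
        error_rate=dict(ERROR_RATES),
        seed=seed,
    )
    params.update(overrides)
    return SubjectProfile(**params)


def older_profile(seed: int = 0, **overrides) -> SubjectProfile:
    """Default older-adult profile: flat, low theta; no reliable coupling;
    slower, more variable RTs."""
    mu, sigma = _rt_params("older")
    params = dict(
        group="older",
        theta_db={"repeat": 0.34, "ID": 0.34, "ED": 0.34},
        rt_mu=mu,
        rt_sigma=sigma,
        coupling_rho={c: float(np.tanh(-0.025)) for c in CONDITIONS},
        error_rate=dict(ERROR_RATES),
        seed=seed,
    )
    params.update(overrides)
    return SubjectProfile(**params)


# --------------------------------------------------------------------------
# background noise

def noise_psd(freqs: np.ndarray, exponent: float, noise_uv: float,
              f_low: float = 0.5) -> np.ndarray:
    """One-sided PSD (uV^2/Hz) of the 1/f background, flattened below f_low;
    scaled so the 1-100 Hz band variance is noise_uv^2."""
    if exponent == 1.0:
        band = np.log(100.0)
    else:
        band = (100.0 ** (1 - exponent) - 1.0) / (1 - exponent)
    amp = noise_uv**2 / band
    f = np.maximum(np.abs(freqs), f_low)
    s = amp * f ** (-exponent)
    s[np.abs(freqs) < 1e-12] = 0.0
    return s


def synth_background(n_ch: int, n_samples: int, fs: float, exponent: float,
                     noise_uv: float, rng: np.random.Generator) -> np.ndarray:
    """1/f background noise, independent channels, exact target PSD."""
    nfast = scipy.fft.next_fast_len(n_samples)
    freqs = np.fft.rfftfreq(nfast, 1.0 / fs)
    scale = np.sqrt(noise_psd(freqs, exponent, noise_uv) * fs * nfast / 4.0)
    scale = scale.astype(np.float32)
    out = np.empty((n_ch, n_samples), dtype=np.float32)
    for ch in range(n_ch):
        z = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
        x = scipy.fft.irfft((scale * z).astype(np.complex64), n=nfast)
        out[ch] = x[:n_samples]
    return out


# --------------------------------------------------------------------------
# burst calibration

def _hann_burst(times: np.ndarray, window: tuple[float, float], freq: float,
                phase: float) -> np.ndarray:
    t0, t1 = window
    env = np.zeros_like(times)
    sel = (times >= t0) & (times <= t1)
    env[sel] = 0.5 * (1 - np.cos(2 * np.pi * (times[sel] - t0) / (t1 - t0)))
    return env * np.cos(2 * np.pi * freq * times + phase)


@functools.lru_cache(maxsize=None)
def _wavelet_noise_floor(key: tuple) -> np.ndarray:
    """E[wavelet power] of the background per analysis frequency (uV^2)."""
    fs, exponent, noise_uv, band = key
    freqs = np.asarray(band)
    nfft = 1 << 17
    grid = np.fft.fftfreq(nfft, 1.0 / fs)
    dnu = fs / nfft
    two_sided = noise_psd(grid, exponent, noise_uv) / 2.0
    out = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        w = _tfr.morlet_wavelet(f, fs)
        g = scipy.fft.fft(w, nfft) / fs
        out[i] = float(np.sum(two_sided * np.abs(g) ** 2) * dnu)
    return out


@functools.lru_cache(maxsize=None)
def _burst_box_template(key: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Wavelet power of a unit-amplitude burst over the analysis box.

    Returns (act, base): act is (n_band_freqs, n_box_times) power in the
    analysis box window, base is (n_band_freqs,) mean power leaking into the
    baseline window.  Averaged over the burst frequency-jitter distribution
    (Gauss-Hermite) and two quadrature phases.
    """
    fs, f0, jitter, w0, w1, band, box0, box1 = key
    times = np.arange(round(-1.25 * fs), round(1.6 * fs) + 1) / fs
    nodes, weights = np.polynomial.hermite_e.hermegauss(5)
    freqs_j = f0 + jitter * nodes
    rows, wts = [], []
    for fj, wj in zip(freqs_j, weights / weights.sum()):
        for ph in (0.0, np.pi / 2):
            rows.append(_hann_burst(times, (w0, w1), fj, ph))
            wts.append(wj / 2.0)
    data = np.asarray(rows, dtype=np.float32)[:, None, :]
    ep = Epochs(data=data, times=times, fs=fs, ch_names=("tmpl",),
                info=pd.DataFrame({"row": range(len(rows))}))
    t = _tfr.morlet_power(ep, freqs=np.asarray(band))
    wts = np.asarray(wts)[:, None, None]
    tsel = (t.times >= box0 - 1e-9) & (t.times <= box1 + 1e-9)
    bsel = (t.times >= _tfr.BASELINE_WINDOW[0] - 1e-9) & (t.times <= _tfr.BASELINE_WINDOW[1] + 1e-9)
    pw = t.power[:, 0]  # (rows, n_f, n_t)
    act = np.sum(pw[:, :, tsel] * wts, axis=0)
    base = np.sum(pw[:, :, bsel] * wts, axis=0).mean(axis=1)
    return act, base


def _expected_shepherd_z(r: float, sig: float, gain: float,
                         cross_unit: np.ndarray, noise_box: np.ndarray,
                         s: float, n_trials: int, rng: np.random.Generator,
                         n_datasets: int = 300) -> float:
    """Mean Fisher z of Shepherd's Pi over simulated participant cells.

    Each dataset mirrors one participant x condition cell: `n_trials` single
    trial theta values assembled from the pilot noise/cross samples and a
    latent Gaussian correlation `r` with the RT score.
    """
    from .singletrial import shepherds_pi

    zs = np.empty(n_datasets)
    for k in range(n_datasets):
        z1 = rng.standard_normal(n_trials)
        z2 = r * z1 + np.sqrt(1 - r * r) * rng.standard_normal(n_trials)
        q = np.exp(s * z1 - s**2 / 2.0)
        j = rng.integers(0, len(noise_box), size=n_trials)
        m = q * sig + gain * np.sqrt(q) * cross_unit[j] + noise_box[j]
        res = shepherds_pi(m, z2, rng=rng)
        zs[k] = res.fisher_z if res.valid else 0.0
    return float(zs.mean())


def spatial_weights(positions: np.ndarray, centre: np.ndarray,
                    sigma: float) -> np.ndarray:
    """Gaussian weights in great-circle distance around `centre` (unit sphere)."""
    cosd = np.clip(positions @ centre, -1.0, 1.0)
    d = np.arccos(cosd)
    return np.exp(-(d**2) / (2.0 * sigma**2))


@dataclass
class BurstCalibration:
    """Deterministic calibration of the generative model for one profile."""

    band_freqs: np.ndarray
    noise_floor: np.ndarray  # per band frequency, uV^2
    gains: dict[str, float]  # condition -> amplitude gain (uV)
    occipital_gain: float
    latent_r: dict[str, float]  # condition -> Gaussian-copula correlation
    frontocentral_weights: np.ndarray  # per midfrontal electrode
    signal_box_power: dict[str, float]  # condition -> mean burst power in box


@functools.lru_cache(maxsize=None)
def _box_noise_pilot(key: tuple) -> tuple[np.ndarray, np.ndarray, float]:
    """Pilot transform of background-only epochs through the analysis box.

    Returns per-epoch samples of (a) the box-mean noise power and (b) the
    burst-noise interference term for a unit-amplitude burst (the 2*Re(S N*)
    cross term of wavelet power), plus the box power of the unit burst
    itself.  Epochs are re-referenced against a simulated mastoid pair so the
    samples carry the reference-noise contribution and the across-channel
    correlation it induces.  Deterministic via a fixed internal seed.
    """
    fs, exponent, noise_uv, band, weights, f0, w0, w1 = key
    weights = np.asarray(weights)
    n_ch = len(weights)
    n_epochs = 200
    rng = np.random.default_rng(12345)
    times = np.arange(round(-1.25 * fs), round(1.40 * fs) + 1) / fs
    n_t = len(times)
    data = synth_background(n_epochs * (n_ch + 2), n_t, fs, exponent, noise_uv, rng)
    data = data.reshape(n_epochs, n_ch + 2, n_t)
    noise = data[:, :n_ch] - data[:, n_ch:].mean(axis=1, keepdims=True)
    burst = (weights[:, None] * _hann_burst(times, (w0, w1), f0, 0.0)[None, :]
             ).astype(np.float32)
    names = tuple(f"ch{i}" for i in range(n_ch))

    def box(arr: np.ndarray) -> np.ndarray:
        ep = Epochs(data=arr, times=times, fs=fs, ch_names=names,
                    info=pd.DataFrame({"trial": range(len(arr))}))
        t = _tfr.morlet_power(ep, freqs=np.asarray(band))
        tsel = (t.times >= _tfr.THETA_WINDOW[0] - 1e-9) & (
            t.times <= _tfr.THETA_WINDOW[1] + 1e-9)
        return t.power[:, :, :, tsel].mean(axis=(1, 2, 3))

    noise_box = box(noise)
    with_burst_box = box(noise + burst[None, :, :])
    unit_box = float(box(burst[None, :, :])[0])
    cross = with_burst_box - noise_box - unit_box
    return noise_box, cross, unit_box


_CALIBRATION_CACHE: dict = {}


def calibrate_profile(profile: SubjectProfile,
                      montage: tuple[str, ...] = MONTAGE_64,
                      fs: float = _ANALYSIS_FS) -> BurstCalibration:
    """Solve for burst gains and copula correlations hitting the profile's
    pipeline-level targets, against the analytic noise floor.

    Deterministic and seed-independent: the result depends only on the
    profile's generative parameters (not its seed), so it is memoized.
    """
    cache_key = (
        tuple(sorted(profile.theta_db.items())),
        tuple(sorted(profile.coupling_rho.items())),
        profile.occipital_evoked_db, profile.noise_exponent, profile.noise_uv,
        profile.amp_sigma, profile.burst_freq, profile.burst_freq_jitter,
        profile.burst_window, profile.occipital_window, profile.spatial_sigma,
        tuple(montage), fs,
    )
    if cache_key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[cache_key]
    band = tuple(f for f in range(1, 61)
                 if _tfr.THETA_BAND[0] <= f <= _tfr.THETA_BAND[1])
    pn = _wavelet_noise_floor((fs, profile.noise_exponent, profile.noise_uv, band))
    act, base = _burst_box_template(
        (fs, profile.burst_freq, profile.burst_freq_jitter,
         profile.burst_window[0], profile.burst_window[1], band,
         _tfr.THETA_WINDOW[0], _tfr.THETA_WINDOW[1])
    )
    positions = montage_positions(montage)
    name_to_pos = dict(zip(montage, positions))
    centre = name_to_pos["FCz"]

    def weights_for(chs, c, sigma):
        w = np.array([
            spatial_weights(name_to_pos[ch][None, :], c, sigma)[0] for ch in chs
        ])
        w_mast = np.array([
            spatial_weights(name_to_pos[m][None, :], c, sigma)[0]
            for m in ("TP9", "TP10")
        ]).mean()
        return w - w_mast  # linked-mastoid reference subtracts its burst share

    w_mid = weights_for(MIDFRONTAL_ELECTRODES, centre, profile.spatial_sigma)

    # the mastoid reference adds half a channel's background variance
    pn = pn * 1.5

    # r_cell: burst power per (electrode, freq, time) relative to noise floor
    r_act = (w_mid[:, None, None] ** 2) * act[None, :, :] / pn[None, :, None]
    r_base = (w_mid[:, None] ** 2) * base[None, :] / pn[None, :]

    weights = CONDITION_TRIAL_WEIGHTS

    def solve_gains(leak: np.ndarray) -> dict[str, float]:
        gains = {}
        for c in CONDITIONS:
            target = profile.theta_db[c]
            if target == 0.0:
                gains[c] = 0.0
                continue

            def f(g2: float) -> float:
                num = 1.0 + g2 * r_act
                den = (1.0 + leak)[:, :, None] * np.ones_like(num)
                return float(np.mean(10 * np.log10(num / den))) - target

            gains[c] = float(np.sqrt(brentq(f, 0.0, 1e8)))
        return gains

    leak = np.zeros_like(r_base)
    gains = solve_gains(leak)
    for _ in range(3):  # fixed-point on the common-baseline leak
        leak = sum(weights[c] * gains[c] ** 2 for c in CONDITIONS) * r_base
        gains = solve_gains(leak)

    # occipital evoked burst: calibrated against its own box, no leak terms
    occ_act, _ = _burst_box_template(
        (fs, profile.burst_freq, profile.burst_freq_jitter,
         profile.occipital_window[0], profile.occipital_window[1], band,
         profile.occipital_window[0], profile.occipital_window[1])
    )
    w_occ = weights_for(
        tuple(ch for ch in OCCIPITAL_ELECTRODES if ch in montage),
        name_to_pos["Oz"], 0.5)
    occ_r = (w_occ[:, None, None] ** 2) * occ_act[None, :, :] / pn[None, :, None]
    d_occ = profile.occipital_evoked_db
    if d_occ <= 0:
        occ_gain = 0.0
    else:
        occ_gain = float(np.sqrt(brentq(
            lambda g2: float(np.mean(10 * np.log10(1.0 + g2 * occ_r))) - d_occ,
            0.0, 1e8)))

    # copula correction for rank-correlation attenuation by measurement noise:
    # the single-trial theta estimate is q * S + g * sqrt(q) * X + N, with
    # (X, N) the burst-noise interference and box-noise samples from the
    # pilot transform; the latent Gaussian correlation is inflated so the
    # post-pipeline Spearman correlation meets the profile target.
    noise_box, cross_unit, unit_box = _box_noise_pilot(
        (fs, profile.noise_exponent, profile.noise_uv, band, tuple(w_mid),
         profile.burst_freq, profile.burst_window[0], profile.burst_window[1]))
    sig_box = {c: gains[c] ** 2 * unit_box for c in CONDITIONS}
    rng = np.random.default_rng(987654321)
    n_mc = 20000
    z1 = rng.standard_normal(n_mc)
    j = rng.integers(0, len(noise_box), size=n_mc)
    latent_r = {}
    s = 2.0 * profile.amp_sigma
    for c in CONDITIONS:
        rho_t = profile.coupling_rho[c]
        if sig_box[c] <= 0 or rho_t == 0.0:
            latent_r[c] = 2.0 * np.sin(np.pi * rho_t / 6.0)
            continue
        q = np.exp(s * z1 - s**2 / 2.0)
        m = q * sig_box[c] + gains[c] * np.sqrt(q) * cross_unit[j] + noise_box[j]
        ranks = pd.Series(m).rank().to_numpy()
        nscore = norm.ppf((ranks - 0.5) / len(ranks))
        a = float(np.corrcoef(nscore, z1)[0, 1])
        r = 2.0 * np.sin(np.pi * rho_t / 6.0) / max(a, 1e-6)
        # second correction: forward Monte-Carlo of the actual estimator
        # (Shepherd's Pi truncates the heavy right tail of single-trial
        # power, attenuating rank correlations beyond the noise effect)
        n_c = int(round(200 * CONDITION_TRIAL_WEIGHTS[c]))
        z_hat = _expected_shepherd_z(
            r, sig_box[c], gains[c], cross_unit, noise_box, s, n_c, rng)
        target_z = float(np.arctanh(rho_t))
        if abs(z_hat) > 1e-6:
            r = r * target_z / z_hat
        if abs(r) >= 1.0:
            raise ProfileError(
                f"coupling_rho={rho_t} for condition {c!r} is unreachable "
                "under the configured noise floor")
        latent_r[c] = float(r)

    result = BurstCalibration(
        band_freqs=np.asarray(band, dtype=float),
        noise_floor=pn,
        gains=gains,
        occipital_gain=occ_gain,
        latent_r=latent_r,
        frontocentral_weights=w_mid,
        signal_box_power=sig_box,
    )
    _CALIBRATION_CACHE[cache_key] = result
    return result


# --------------------------------------------------------------------------
# behaviour

def sample_rt(profile: SubjectProfile, condition: str,
              rng: np.random.Generator) -> tuple[float | None, str]:
    """One (rt_ms, response) draw: log-normal RT with condition/group offsets.

    With probability `error_rate` the response lands on the wrong side; draws
    beyond the 4 s deadline become no-responses.  Returns (None, "none") for
    no-response trials.
    """
    mu = profile.param(profile.rt_mu, condition)
    sigma = profile.param(profile.rt_sigma, condition)
    rt = float(np.exp(mu + sigma * rng.standard_normal()))
    if rt > RESPONSE_DEADLINE_MS:
        return None, "none"
    side = "wrong" if rng.random() < profile.param(profile.error_rate, condition) else "correct"
    return rt, side


def _draw_trials(profile: SubjectProfile, sequence: TrialSequence,
                 rng: np.random.Generator,
                 calibration: BurstCalibration | None) -> pd.DataFrame:
    """Per-trial latent draws: RT, response, burst amplitude multiplier."""
    rows = []
    s = 2.0 * profile.amp_sigma
    for t in sequence:
        cond = t.condition or "filler"
        r = calibration.latent_r["repeat" if cond == "filler" else cond] if calibration else 0.0
        z1 = rng.standard_normal()
        z2 = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal()
        mu = profile.param(profile.rt_mu, cond)
        sigma = profile.param(profile.rt_sigma, cond)
        rt = float(np.exp(mu + sigma * z2))
        if rt > RESPONSE_DEADLINE_MS:
            response, rt_rec = "none", None
        elif rng.random() < profile.param(profile.error_rate, cond):
            response = "left" if t.correct_side == "right" else "right"
            rt_rec = rt
        else:
            response, rt_rec = t.correct_side, rt
        correct = score_response(t, response, rt if rt_rec is not None else RESPONSE_DEADLINE_MS)
        rows.append({
            "trial": t.index,
            "block": t.block,
            "condition": cond,
            "rt_ms": rt_rec,
            "display_ms": rt if rt_rec is not None else RESPONSE_DEADLINE_MS,
            "response": response,
            "correct": correct == "correct",
            "q": float(np.exp(s * z1 - s**2 / 2.0)),
            "burst_freq": float(np.clip(
                profile.burst_freq + profile.burst_freq_jitter * rng.standard_normal(),
                4.2, 7.8)),
            "phase": float(rng.uniform(0, 2 * np.pi)),
        })
    return pd.DataFrame(rows)


def simulate_behaviour(profile: SubjectProfile, sequence: TrialSequence,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Behaviour-only simulation (no EEG): one row per trial."""
    rng = rng or np.random.default_rng(profile.seed)
    df = _draw_trials(profile, sequence, rng, calibration=None)
    return df.drop(columns=["q", "burst_freq", "phase"])


# --------------------------------------------------------------------------
# EEG assembly

def simulate_subject(profile: SubjectProfile, sequence: TrialSequence | None = None,
                     fs: float = 1000.0, montage: tuple[str, ...] = MONTAGE_64,
                     calibration: BurstCalibration | None = None,
                     ) -> tuple[EEGRecording, pd.DataFrame]:
    """Simulate one participant's continuous EEG and behaviour.

    Deterministic for a fixed `profile.seed`.  The recording is 1/f
    background plus per-trial midfrontal and occipital theta bursts; burst
    amplitudes and RTs are coupled through the calibrated Gaussian copula.
    """
    rng = np.random.default_rng(profile.seed)
    if sequence is None:
        sequence = generate_sequence(TaskConfig(), seed=int(rng.integers(2**31)))
    if calibration is None:
        calibration = calibrate_profile(profile, montage=montage)

    trials = _draw_trials(profile, sequence, rng, calibration)

    # trial timeline: fixation 800-1300 ms, stimulus until response (<= 4 s),
    # 1 s blank
    fix = rng.uniform(0.8, 1.3, size=len(trials))
    onsets = np.empty(len(trials))
    cursor = 3.0  # front padding so the first epoch fits
    for i in range(len(trials)):
        cursor += fix[i]
        onsets[i] = cursor
        cursor += trials["display_ms"].iloc[i] / 1000.0 + 1.0
    n_samples = int(round((cursor + 4.0) * fs))

    data = synth_background(len(montage), n_samples, fs,
                            profile.noise_exponent, profile.noise_uv, rng)
    if profile.line_noise_uv > 0:
        tgrid = np.arange(n_samples) / fs
        line = profile.line_noise_uv * np.sin(
            2 * np.pi * profile.line_noise_hz * tgrid + rng.uniform(0, 2 * np.pi))
        data += line.astype(np.float32)[None, :]

    positions = montage_positions(montage)
    name_to_pos = dict(zip(montage, positions))
    w_front = spatial_weights(positions, name_to_pos["FCz"], profile.spatial_sigma)
    w_occ = spatial_weights(positions, name_to_pos["Oz"], 0.5)

    bw0, bw1 = profile.burst_window
    ow0, ow1 = profile.occipital_window
    tb = np.arange(round(bw0 * fs), round(bw1 * fs) + 1) / fs
    to = np.arange(round(ow0 * fs), round(ow1 * fs) + 1) / fs
    events = np.empty((len(trials), 2), dtype=np.int64)
    for i, row in trials.iterrows():
        onset = int(round(onsets[i] * fs))
        events[i] = (onset, row["trial"] + 1)
        cond = "repeat" if row["condition"] == "filler" else row["condition"]
        g = calibration.gains[cond]
        if g > 0:
            amp = g * np.sqrt(row["q"])
            burst = amp * _hann_burst(tb, (bw0, bw1), row["burst_freq"], row["phase"])
            sl = slice(onset + int(round(bw0 * fs)), onset + int(round(bw0 * fs)) + len(tb))
            data[:, sl] += (w_front[:, None] * burst[None, :]).astype(np.float32)
        if calibration.occipital_gain > 0:
            oamp = calibration.occipital_gain * float(
                np.exp(0.25 * rng.standard_normal() - 0.25**2))
            oburst = oamp * _hann_burst(to, (ow0, ow1), profile.burst_freq,
                                        rng.uniform(0, 2 * np.pi))
            sl = slice(onset + int(round(ow0 * fs)), onset + int(round(ow0 * fs)) + len(to))
            data[:, sl] += (w_occ[:, None] * oburst[None, :]).astype(np.float32)

    rec = EEGRecording(ch_names=tuple(montage), positions=positions, fs=fs,
                       data=data, events=events)
    behaviour = trials.drop(columns=["q", "burst_freq", "phase"])
    return rec, behaviour


# --------------------------------------------------------------------------
# cohort simulation

def cohort_profiles(n_young: int = 20, n_older: int = 19,
                    master_seed: int = 0) -> list[SubjectProfile]:
    """Per-subject profiles with seeds split off a master seed."""
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_young + n_older)]
    profiles = [young_profile(seed=seeds[i]) for i in range(n_young)]
    profiles += [older_profile(seed=seeds[n_young + i]) for i in range(n_older)]
    return profiles


def simulate_cohort(n_young: int = 20, n_older: int = 19, master_seed: int = 0,
                    out_dir: str | Path = ".", task_config: TaskConfig | None = None,
                    fs: float = 1000.0, montage: tuple[str, ...] = MONTAGE_64) -> dict:
    """Simulate a cohort to disk: BrainVision triplet + behaviour TSV per
    subject, plus a YAML manifest.  Returns the manifest dict."""
    import yaml

    from .brainvision import write_brainvision

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = cohort_profiles(n_young, n_older, master_seed)
    manifest = {"master_seed": master_seed, "fs": fs, "montage": list(montage),
                "subjects": []}
    task_config = task_config or TaskConfig()
    for i, profile in enumerate(profiles):
        sid = f"sub-{i + 1:02d}"
        seq = generate_sequence(task_config, seed=profile.seed)
        cal = calibrate_profile(profile, montage=montage)
        rec, behav = simulate_subject(profile, seq, fs=fs, montage=montage,
                                      calibration=cal)
        write_brainvision(rec, out_dir / f"{sid}.vhdr")
        behav.insert(0, "participant", sid)
        behav.to_csv(out_dir / f"{sid}_behaviour.tsv", sep="\t", index=False)
        from .taskgen import write_sequence_tsv

        write_sequence_tsv(seq, out_dir / f"{sid}_trials.tsv")
        manifest["subjects"].append(
            {"id": sid, "group": profile.group, "seed": profile.seed,
             "files": [f"{sid}.vhdr", f"{sid}_behaviour.tsv", f"{sid}_trials.tsv"]})
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
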