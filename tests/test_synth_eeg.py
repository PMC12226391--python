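import numpy as np
import pandas as pd
import pytest
import scipy.signal
import scipy.stats

from ided_theta import synth_eeg as se
from ided_theta import tfr
from ided_theta.data import MIDFRONTAL_ELECTRODES, MONTAGE_16
from ided_theta.taskgen import TaskConfig, generate_sequence
from tests.conftest import make_epochs


class TestProfiles:
    def test_young_condition_ordering(self):
        p = se.young_profile()
        assert p.theta_db["ED"] > p.theta_db["ID"] > p.theta_db["repeat"]

    def test_older_theta_flat_and_low(self):
        p = se.older_profile()
        assert len(set(p.theta_db.values())) == 1
        assert p.theta_db["ED"] < se.young_profile().theta_db["repeat"]

    def test_validation_rejects_bad_error_rate(self):
        p = se.young_profile()
        with pytest.raises(se.ProfileError):
            se.SubjectProfile(**{**p.__dict__,
                                 "error_rate": {c: 1.5 for c in ("repeat", "ID", "ED")}})

    def test_rt_calibration_hits_pooled_median(self):
        """Cohort mean of per-participant analytic medians equals the target."""
        w = np.array([0.5, 0.25, 0.25])
        medians = []
        for prof, n in ((se.young_profile(), 20), (se.older_profile(), 19)):
            mus = np.array([prof.rt_mu[c] for c in ("repeat", "ID", "ED")])
            sig = np.array([prof.rt_sigma[c] for c in ("repeat", "ID", "ED")])
            medians += [se._mixture_median(mus, sig, w)] * n
        assert np.mean(medians) == pytest.approx(se.POOLED_MEDIAN_RT_MS, abs=0.1)

    def test_error_rates_pool_to_reported_mean(self):
        p = se.young_profile()
        assert np.mean(list(p.error_rate.values())) == pytest.approx(0.019, abs=1e-9)


class TestSampleRT:
    def test_degenerate_sigma_returns_exp_mu(self):
        p = se.young_profile()
        p.rt_sigma = {c: 1e-12 for c in ("repeat", "ID", "ED")}
        p.error_rate = {c: 0.0 for c in ("repeat", "ID", "ED")}
        rt, resp = se.sample_rt(p, "ID", np.random.default_rng(0))
        assert rt == pytest.approx(np.exp(p.rt_mu["ID"]), rel=1e-9)
        assert resp == "correct"

    def test_draws_beyond_deadline_become_no_response(self):
        p = se.young_profile()
        p.rt_mu = {c: np.log(5000.0) for c in ("repeat", "ID", "ED")}
        p.rt_sigma = {c: 1e-12 for c in ("repeat", "ID", "ED")}
        rt, resp = se.sample_rt(p, "ED", np.random.default_rng(0))
        assert rt is None and resp == "none"

    def test_error_probability_respected(self):
        p = se.young_profile()
        p.error_rate = {c: 0.5 for c in ("repeat", "ID", "ED")}
        rng = np.random.default_rng(1)
        outcomes = [se.sample_rt(p, "repeat", rng)[1] for _ in range(2000)]
        frac = np.mean([o == "wrong" for o in outcomes])
        assert frac == pytest.approx(0.5, abs=0.05)


class TestBackgroundNoise:
    def test_psd_matches_construction(self):
        rng = np.random.default_rng(0)
        x = se.synth_background(2, 400_000, 1000.0, 1.0, 10.0, rng)
        f, p = scipy.signal.welch(x[0].astype(float), fs=1000.0, nperseg=32768)
        for ff in (2.0, 6.0, 20.0):
            i = np.argmin(np.abs(f - ff))
            target = se.noise_psd(np.array([ff]), 1.0, 10.0)[0]
            assert p[i] == pytest.approx(target, rel=0.25)

    def test_log_log_spectral_slope_matches_exponent(self):
        rng = np.random.default_rng(1)
        for alpha in (0.8, 1.2):
            x = se.synth_background(1, 500_000, 500.0, alpha, 10.0, rng)
            f, p = scipy.signal.welch(x[0].astype(float), fs=500.0, nperseg=16384)
            sel = (f >= 2) & (f <= 50)
            slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
            assert slope == pytest.approx(-alpha, abs=0.1)

    def test_analytic_wavelet_floor_matches_simulation(self):
        rng = np.random.default_rng(2)
        fs = 500.0
        x = se.synth_background(1, 400_000, fs, 1.0, 10.0, rng)[0].astype(float)
        w = tfr.morlet_wavelet(6.0, fs)
        y = np.convolve(x, w) / fs
        emp = float((np.abs(y[len(w):-len(w)]) ** 2).mean())
        ana = se._wavelet_noise_floor((fs, 1.0, 10.0, (4, 5, 6, 7, 8)))[2]
        assert emp == pytest.approx(ana, rel=0.1)


class TestBurstCalibration:
    def test_zero_target_gives_zero_gain(self):
        prof = se.young_profile(theta_db={"repeat": 0.0, "ID": 0.0, "ED": 0.0},
                                coupling_rho={c: 0.0 for c in ("repeat", "ID", "ED")},
                                occipital_evoked_db=0.0)
        cal = se.calibrate_profile(prof, montage=MONTAGE_16)
        assert all(g == 0.0 for g in cal.gains.values())
        assert cal.occipital_gain == 0.0

    def test_gain_monotone_in_target(self):
        cal_y = se.calibrate_profile(se.young_profile(), montage=MONTAGE_16)
        cal_o = se.calibrate_profile(se.older_profile(), montage=MONTAGE_16)
        assert cal_y.gains["ED"] > cal_y.gains["ID"] > cal_y.gains["repeat"]
        assert cal_o.gains["ED"] < cal_y.gains["repeat"]

    def test_analytic_db_identity_on_synthetic_mixture(self):
        """Sinusoid of known wavelet power over noise of known floor gives
        the closed-form 10*log10((Ps+Pn)/Pn) after baseline normalization."""
        rng = np.random.default_rng(3)
        fs = 500.0
        n_tr = 120
        times = np.arange(round(-1.25 * fs), round(3.0 * fs) + 1) / fs
        sigma_n = 5.0
        noise = rng.standard_normal((n_tr, 1, len(times))) * sigma_n
        amp = 2.0
        burst = np.where((times > 0.05) & (times < 1.2),
                         amp * np.cos(2 * np.pi * 6 * times), 0.0)
        ep = make_epochs(noise + burst[None, None, :], fs=fs,
                         conditions=["ID"] * n_tr)
        t = tfr.morlet_power(ep, freqs=np.array([6.0]), auto_decimate=False)
        db = tfr.db_normalize(tfr.trial_average(t),
                              baseline=tfr.compute_baseline(t))
        sel = (t.times >= 0.4) & (t.times <= 0.8)
        measured = float(np.nanmean(db.power[0, 0, 0, sel]))
        sigma_t = tfr.N_CYCLES / (2 * np.pi * 6.0)
        ps = amp**2 / 4 * np.sqrt(4 * np.pi * sigma_t**2)
        pn = sigma_n**2 / fs  # white-noise wavelet floor (unit-energy wavelet)
        expected = 10 * np.log10((ps + pn) / pn)
        assert measured == pytest.approx(expected, abs=0.4)


class TestCoupling:
    def test_copula_spearman_at_half(self):
        """With a pure copula (no measurement noise) the latent correlation
        2*sin(pi*rho/6) reproduces Spearman rho between amplitude and RT."""
        import dataclasses

        prof = se.young_profile(seed=99)
        rho = 0.5
        cal = dataclasses.replace(
            se.calibrate_profile(prof, montage=MONTAGE_16),
            latent_r={c: 2 * np.sin(np.pi * rho / 6)
                      for c in ("repeat", "ID", "ED")})
        seq = generate_sequence(seed=7)
        trials = se._draw_trials(prof, seq, np.random.default_rng(0), cal)
        # pool trials sharing one RT distribution (fillers use repeat params)
        ok = trials["rt_ms"].notna() & trials["condition"].isin(("filler", "repeat"))
        r = scipy.stats.spearmanr(trials.loc[ok, "q"],
                                  trials.loc[ok, "rt_ms"]).statistic
        assert r == pytest.approx(rho, abs=0.07)  # n ~ 460 trials

    def test_zero_coupling_profile_yields_zero_latent(self):
        prof = se.young_profile(coupling_rho={c: 0.0 for c in ("repeat", "ID", "ED")})
        cal = se.calibrate_profile(prof, montage=MONTAGE_16)
        assert all(r == 0.0 for r in cal.latent_r.values())


class TestSimulateSubject:
    def test_deterministic_for_fixed_seed(self):
        prof = se.young_profile(seed=12)
        cal = se.calibrate_profile(prof, montage=MONTAGE_16)
        seq = generate_sequence(TaskConfig(shifts_per_subtype=2, n_blocks=1),
                                seed=5)
        rec1, b1 = se.simulate_subject(prof, seq, montage=MONTAGE_16,
                                       calibration=cal)
        rec2, b2 = se.simulate_subject(prof, seq, montage=MONTAGE_16,
                                       calibration=cal)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        pd.testing.assert_frame_equal(b1, b2)

    def test_events_align_with_trials(self):
        prof = se.young_profile(seed=12)
        cal = se.calibrate_profile(prof, montage=MONTAGE_16)
        seq = generate_sequence(TaskConfig(shifts_per_subtype=2, n_blocks=1),
                                seed=5)
        rec, behav = se.simulate_subject(prof, seq, montage=MONTAGE_16,
                                         calibration=cal)
        assert len(rec.events) == len(seq)
        assert list(rec.events[:, 1]) == [t.index + 1 for t in seq]
        assert np.all(np.diff(rec.events[:, 0]) > 0)

    def test_null_profile_measures_near_zero_db(self):
        """All-zero targets: the pipeline reads back ~0 dB (null model)."""
        from ided_theta import preprocess as pp

        prof = se.young_profile(
            seed=3, theta_db={c: 0.0 for c in ("repeat", "ID", "ED")},
            coupling_rho={c: 0.0 for c in ("repeat", "ID", "ED")},
            occipital_evoked_db=0.0)
        cal = se.calibrate_profile(prof, montage=MONTAGE_16)
        seq = generate_sequence(seed=8)
        rec, behav = se.simulate_subject(prof, seq, montage=MONTAGE_16,
                                         calibration=cal)
        epochs, _ = pp.preprocess_recording(
            rec, behav, analysis_channels=MIDFRONTAL_ELECTRODES)
        t = tfr.morlet_power(epochs, freqs=np.arange(4.0, 9.0))
        db = tfr.db_normalize(tfr.trial_average(t),
                              baseline=tfr.compute_baseline(t))
        out = tfr.extract_midfrontal_theta(db)
        # single-subject null dB has SD ~ 0.2 per condition (shared-baseline
        # noise); bounds at ~3 SE of the pooled mean and per-condition values
        assert np.abs(out["theta_db"].mean()) < 0.45
        assert np.abs(out["theta_db"]).max() < 0.8


class TestCohortIO:
    def test_tiny_cohort_round_trip(self, tmp_path):
        from ided_theta.brainvision import read_brainvision

        config = TaskConfig(shifts_per_subtype=1, n_blocks=1, fillers_per_block=1)
        manifest = se.simulate_cohort(n_young=1, n_older=1, master_seed=3,
                                      out_dir=tmp_path, task_config=config,
                                      montage=MONTAGE_16)
        assert len(manifest["subjects"]) == 2
        sub = manifest["subjects"][0]
        rec = read_brainvision(tmp_path / f"{sub['id']}.vhdr")
        assert rec.fs == 1000.0
        assert rec.ch_names == MONTAGE_16
        raw = np.fromfile(tmp_path / f"{sub['id']}.eeg", dtype="<f4")
        n = rec.n_samples
        np.testing.assert_allclose(
            rec.data[:, :100],
            raw.reshape(n, len(MONTAGE_16)).T[:, :100], rtol=1e-6)

    def test_cohort_determinism(self, tmp_path):
        config = TaskConfig(shifts_per_subtype=1, n_blocks=1, fillers_per_block=1)
        se.simulate_cohort(1, 0, 9, tmp_path / "a", task_config=config,
                           montage=MONTAGE_16)
        se.simulate_cohort(1, 0, 9, tmp_path / "b", task_config=config,
                           montage=MONTAGE_16)
        a = (tmp_path / "a" / "sub-01.eeg").read_bytes()
        b = (tmp_path / "b" / "sub-01.eeg").read_bytes()
        assert a == b

    def test_default_cohort_lists_39_subjects(self):
        profiles = se.cohort_profiles()
        assert len(profiles) == 39
        assert sum(p.group == "young" for p in profiles) == 20
        assert sum(p.group == "older" for p in profiles) == 19
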