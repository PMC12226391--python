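import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ided_theta import stats as st


def make_mixed_data(rng, n_per_group=(8, 6), conds=("repeat", "ID", "ED"),
                    cond_effect=0.0, group_effect=0.0, subject_sd=1.0,
                    noise_sd=0.7):
    rows = []
    for gi, (g, n) in enumerate(zip(("young", "older"), n_per_group)):
        for s in range(n):
            base = rng.normal(0, subject_sd) + gi * group_effect
            for ci, c in enumerate(conds):
                rows.append({
                    "participant": f"{g}-{s}",
                    "group": g,
                    "condition": c,
                    "dv": base + ci * cond_effect + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


class TestBehaviouralMeasures:
    def test_hand_listed_fixture(self):
        behav = pd.DataFrame({
            "participant": "p1",
            "condition": ["ID"] * 6,
            "trial": range(6),
            "rt_ms": [500.0, 600.0, 700.0, 800.0, np.nan, 650.0],
            "correct": [True, True, True, True, False, False],
        })
        out = st.behavioural_measures(behav)
        logs = np.log([500, 600, 700, 800])
        assert out["mean_log_rt"].iloc[0] == pytest.approx(logs.mean())
        assert out["sd_log_rt"].iloc[0] == pytest.approx(logs.std(ddof=1))
        assert out["error_rate"].iloc[0] == pytest.approx(2 / 6)

    def test_constant_rt_gives_zero_sd(self):
        behav = pd.DataFrame({
            "participant": "p1", "condition": ["ED"] * 4, "trial": range(4),
            "rt_ms": [np.e * 1000] * 4, "correct": True,
        })
        out = st.behavioural_measures(behav)
        assert out["mean_log_rt"].iloc[0] == pytest.approx(1 + np.log(1000))
        assert out["sd_log_rt"].iloc[0] == 0.0

    def test_ten_trials_one_error(self):
        behav = pd.DataFrame({
            "participant": "p1", "condition": ["repeat"] * 10, "trial": range(10),
            "rt_ms": [600.0] * 10,
            "correct": [True] * 9 + [False],
        })
        assert st.behavioural_measures(behav)["error_rate"].iloc[0] == pytest.approx(0.10)


class TestPerformanceZ:
    def _fixture(self):
        # 3 young + 1 older participant, one condition: weights differ
        scores = pd.DataFrame({
            "participant": ["a", "b", "c", "d"],
            "condition": "ID",
            "error_rate": [0.0, 0.1, 0.2, 0.3],
            "mean_log_rt": [6.0, 6.2, 6.4, 6.8],
            "sd_log_rt": [0.2, 0.25, 0.3, 0.4],
        })
        groups = {"a": "young", "b": "young", "c": "young", "d": "older"}
        return scores, groups

    def test_matches_spreadsheet_computation(self):
        scores, groups = self._fixture()
        out = st.performance_z(scores, groups)
        # weights: young 4/(2*3)=2/3, older 4/(2*1)=2
        w = np.array([2 / 3, 2 / 3, 2 / 3, 2.0])
        expected = np.zeros(4)
        for m in ("error_rate", "mean_log_rt", "sd_log_rt"):
            v = scores[m].to_numpy()
            mean = np.sum(w * v) / w.sum()
            sd = np.sqrt(np.sum(w * (v - mean) ** 2) / w.sum())
            expected -= (v - mean) / sd
        np.testing.assert_allclose(out["z_composite"].to_numpy(), expected)

    def test_participant_at_weighted_mean_scores_zero(self):
        scores, groups = self._fixture()
        out = st.performance_z(scores, groups)
        w = np.array([2 / 3, 2 / 3, 2 / 3, 2.0])
        # construct a fifth participant sitting exactly at the weighted means
        means = {m: np.sum(w * scores[m].to_numpy()) / w.sum()
                 for m in ("error_rate", "mean_log_rt", "sd_log_rt")}
        # z of that point is 0 for every measure by construction
        for m, mu in means.items():
            v = scores[m].to_numpy()
            sd = np.sqrt(np.sum(w * (v - mu) ** 2) / w.sum())
            assert (mu - mu) / sd == 0.0

    def test_better_performance_increases_composite(self):
        scores, groups = self._fixture()
        out1 = st.performance_z(scores, groups)
        improved = scores.copy()
        improved.loc[0, "error_rate"] = 0.0
        improved.loc[1, "error_rate"] = 0.05  # fewer errors for participant b
        out2 = st.performance_z(improved, groups)
        assert out2["z_composite"].iloc[1] > out1["z_composite"].iloc[1]


class TestMixedAnova:
    def test_ss_decomposition_is_exact(self):
        rng = np.random.default_rng(0)
        df = make_mixed_data(rng, cond_effect=0.4, group_effect=0.5)
        res = st.mixed_anova(df, "dv", "condition", "participant", "group")
        tab = res.table
        wide = df.pivot_table(index=["participant", "group"],
                              columns="condition", values="dv")
        y = wide.to_numpy()
        grand = y.mean()
        # brute force: total SS must equal the sum of all strata
        ss_total = float(((y - grand) ** 2).sum())
        # grand-mean correction differs with unequal n; recompute via model
        ss_sum = tab["SS"].sum() + tab["SS_error"].drop_duplicates().sum()
        assert ss_sum == pytest.approx(ss_total, rel=1e-9)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(1)
        df = make_mixed_data(rng, cond_effect=0.3, group_effect=0.4)
        mine = st.mixed_anova(df, "dv", "condition", "participant", "group").table
        ref = pg.mixed_anova(data=df, dv="dv", within="condition",
                             subject="participant", between="group",
                             correction=True)
        for eff, source in (("group", "group"), ("condition", "condition"),
                            ("group*condition", "Interaction")):
            a = mine[mine.effect == eff].iloc[0]
            b = ref[ref.Source == source].iloc[0]
            assert a["SS"] == pytest.approx(b["SS"], rel=1e-9)
            assert a["F"] == pytest.approx(b["F"], rel=1e-9)
            assert a["np2"] == pytest.approx(b["np2"], rel=1e-9)
        eps_mine = mine[mine.effect == "condition"]["eps"].iloc[0]
        eps_ref = ref[ref.Source == "condition"]["eps"].iloc[0]
        assert eps_mine == pytest.approx(eps_ref, rel=0.05)

    def test_gg_epsilon_one_under_compound_symmetry(self):
        sigma = 0.3 * np.ones((3, 3)) + 0.7 * np.eye(3)
        c = st._orthonormal_contrasts(4)[:3, :2]  # any orthonormal pair
        c = st._orthonormal_contrasts(3)
        proj = c.T @ sigma @ c
        assert st._gg_epsilon(proj) == pytest.approx(1.0, abs=1e-12)

    def test_epsilon_lower_bound(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((3, 3))
        sigma = a @ a.T + np.diag([5.0, 0.01, 0.01])
        c = st._orthonormal_contrasts(3)
        eps = st._gg_epsilon(c.T @ sigma @ c)
        assert 0.5 <= eps <= 1.0  # bound 1/(k-1) = 0.5 for k = 3

    def test_degenerate_constant_dv_flagged(self):
        df = make_mixed_data(np.random.default_rng(3))
        df["dv"] = 1.0
        with pytest.raises(st.StatsError):
            st.mixed_anova(df, "dv", "condition", "participant", "group")

    def test_type_one_error_calibration(self):
        """Null simulation: each effect rejects at ~ the nominal 5% rate."""
        rng = np.random.default_rng(12345)
        rejections = np.zeros(3)
        n_rep = 400
        for _ in range(n_rep):
            df = make_mixed_data(rng, n_per_group=(10, 9))
            tab = st.mixed_anova(df, "dv", "condition", "participant",
                                 "group").table
            rejections += (tab["p"].to_numpy() < 0.05)
        rates = rejections / n_rep
        # binomial 99% CI half-width at p=0.05, n=400 is ~0.028
        assert np.all(rates > 0.02) and np.all(rates < 0.09)


class TestThreeWayMixedAnova:
    def test_single_level_factor_reduces_to_two_way(self):
        rng = np.random.default_rng(4)
        df = make_mixed_data(rng, cond_effect=0.5)
        df["electrode"] = "FCz"
        r2 = st.mixed_anova(df, "dv", "condition", "participant", "group").table
        r3 = st.three_way_mixed_anova(df, "dv", ["condition", "electrode"],
                                      "participant", "group").table
        for eff in ("group", "condition", "group*condition"):
            assert r3[r3.effect == eff]["F"].iloc[0] == pytest.approx(
                r2[r2.effect == eff]["F"].iloc[0])

    def test_brute_force_ss_oracle(self):
        """Explicit mean-based sums of squares on a tiny balanced design."""
        rng = np.random.default_rng(5)
        conds, els = ("repeat", "ID"), ("Fz", "Cz", "Oz")
        rows = []
        for g, n in (("young", 4), ("older", 4)):
            for s in range(n):
                for c in conds:
                    for e in els:
                        rows.append({"participant": f"{g}{s}", "group": g,
                                     "condition": c, "electrode": e,
                                     "dv": rng.normal()})
        df = pd.DataFrame(rows)
        res = st.three_way_mixed_anova(df, "dv", ["condition", "electrode"],
                                       "participant", "group").table
        # oracle: balanced-design textbook SS for the condition main effect
        grand = df["dv"].mean()
        ss_cond = 0.0
        for c in conds:
            m = df[df.condition == c]["dv"].mean()
            ss_cond += len(df[df.condition == c]) * (m - grand) ** 2
        assert res[res.effect == "condition"]["SS"].iloc[0] == pytest.approx(
            ss_cond, rel=1e-9)
        # and the electrode main effect
        ss_el = 0.0
        for e in els:
            m = df[df.electrode == e]["dv"].mean()
            ss_el += len(df[df.electrode == e]) * (m - grand) ** 2
        assert res[res.effect == "electrode"]["SS"].iloc[0] == pytest.approx(
            ss_el, rel=1e-9)

    def test_null_three_way_calibration(self):
        rng = np.random.default_rng(99)
        n_rep = 150
        rej = 0
        for _ in range(n_rep):
            rows = []
            for g, n in (("young", 8), ("older", 7)):
                for s in range(n):
                    base = rng.normal()
                    for c in ("repeat", "ID", "ED"):
                        for e in ("Fz", "Cz"):
                            rows.append({"participant": f"{g}{s}", "group": g,
                                         "condition": c, "electrode": e,
                                         "dv": base + rng.normal()})
            tab = st.three_way_mixed_anova(
                pd.DataFrame(rows), "dv", ["condition", "electrode"],
                "participant", "group").table
            rej += tab[tab.effect == "group*condition*electrode"]["p"].iloc[0] < 0.05
        assert 0.01 < rej / n_rep < 0.11


class TestPosthocAndFdr:
    def test_identical_vectors_exact_null(self):
        x = np.arange(5.0)
        out = st.posthoc_tests([("same", x, x.copy())], kind="paired")
        row = out.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0 and row["cohen_d"] == 0.0

    def test_constant_shift_zero_variance_flagged(self):
        x = np.arange(5.0)
        with pytest.raises(st.StatsError):
            st.posthoc_tests([("shift", x + 1.0, x)], kind="paired")

    def test_t_and_d_match_closed_form(self):
        x = np.array([3.1, 2.9, 3.4, 3.8, 2.7])
        y = np.array([2.5, 2.6, 2.9, 3.1, 2.2])
        out = st.posthoc_tests([("xy", x, y)], kind="paired").iloc[0]
        diff = x - y
        t_manual = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert out["t"] == pytest.approx(t_manual)
        assert out["cohen_d"] == pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_bh_step_up_formula(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = st.fdr_adjust(p)
        m = len(p)
        raw = p * m / np.arange(1, m + 1)
        expected = np.minimum.accumulate(raw[::-1])[::-1]
        np.testing.assert_allclose(adj, np.minimum(expected, 1.0))

    def test_bh_all_equal(self):
        np.testing.assert_allclose(st.fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_bh_single_p_unchanged(self):
        assert st.fdr_adjust([0.31])[0] == pytest.approx(0.31)

    def test_bh_monotone_adjusted_geq_raw_for_largest(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=10)
        adj = st.fdr_adjust(p)
        assert adj[np.argmax(p)] >= p.max() - 1e-12


class TestBayes:
    @staticmethod
    def quadrature_bf10(t, n, r=np.sqrt(2) / 2):
        """Dense-grid marginal likelihood ratio with a Cauchy effect prior."""
        nu = n - 1
        delta = np.linspace(-30, 30, 40001)
        prior = scipy.stats.cauchy.pdf(delta, scale=r)
        like = scipy.stats.nct.pdf(t, nu, delta * np.sqrt(n))
        marg1 = np.trapezoid(like * prior, delta)
        marg0 = scipy.stats.t.pdf(t, nu)
        return marg1 / marg0

    def test_bf_matches_quadrature_oracle(self):
        bf = st.bayes_ttest_from_t(6.04, 20)
        assert bf == pytest.approx(self.quadrature_bf10(6.04, 20), rel=0.05)

    def test_null_t_gives_evidence_for_null(self):
        assert st.bayes_ttest_from_t(0.0, 25) < 1.0

    def test_monotone_in_t(self):
        bfs = [st.bayes_ttest_from_t(t, 20) for t in (0.0, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_one_sample_interface(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.8, 1.0, 20)
        t = scipy.stats.ttest_1samp(x, 0.0).statistic
        assert st.bayes_ttest(x) == pytest.approx(
            st.bayes_ttest_from_t(float(t), 20))

    def test_zero_variance_rejected(self):
        with pytest.raises(st.StatsError):
            st.bayes_ttest(np.ones(10))
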