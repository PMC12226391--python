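"""Behavioural and theta statistics: composite performance scores, mixed
ANOVAs with sphericity handling, post-hoc tests, FDR and Bayes factors.

The mixed ANOVA is a univariate split-plot decomposition supporting one
between-subjects factor and one or two within-subjects factors with unequal
group sizes.  Within-subject terms are built from orthonormal contrasts of
the within-cell means; each term carries its own subject-by-term error
stratum, Greenhouse-Geisser epsilon and Mauchly sphericity test.  The
two-way version is cross-checked against pingouin in the test suite.

Composite performance z-scores follow

    z = -(z_error + z_logRT + z_SDlogRT),

with the standardization mean and SD computed across all participants and
conditions under equal-group weighting (each participant weighted by
N_total / (2 * N_group)) so that age groups of unequal size contribute
equally; higher scores mean better performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("repeat", "ID", "ED")


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# behavioural measures and composite scores

def behavioural_measures(behav: pd.DataFrame,
                         conditions=CONDITIONS) -> pd.DataFrame:
    """Per participant x condition: mean/SD of natural-log RTs of correct
    trials and the error rate (fraction incorrect or no-response)."""
    rows = []
    for (participant, condition), cell in behav.groupby(["participant", "condition"]):
        if condition not in conditions:
            continue
        correct = cell[cell["correct"].astype(bool)]
        rts = correct["rt_ms"].dropna().to_numpy()
        if len(rts) == 0:
            rows.append({"participant": participant, "condition": condition,
                         "mean_log_rt": np.nan, "sd_log_rt": np.nan,
                         "error_rate": 1.0 - len(correct) / len(cell),
                         "n_trials": len(cell), "missing": True})
            continue
        logs = np.log(rts)
        rows.append({
            "participant": participant,
            "condition": condition,
            "mean_log_rt": float(logs.mean()),
            "sd_log_rt": float(logs.std(ddof=1)) if len(logs) > 1 else 0.0,
            "error_rate": 1.0 - len(correct) / len(cell),
            "n_trials": len(cell),
            "missing": False,
        })
    out = pd.DataFrame(rows)
    if out["missing"].any():
        import warnings

        warnings.warn("cells without correct trials excluded from RT statistics")
    return out


def performance_z(scores: pd.DataFrame, groups: pd.Series | dict,
                  measures=("error_rate", "mean_log_rt", "sd_log_rt")) -> pd.DataFrame:
    """Composite performance z-score per participant x condition.

    `groups` maps participant -> group label.  Standardization uses the
    equal-group weighted mean and SD across all participants and conditions.
    """
    df = scores.copy()
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    df["group"] = df["participant"].map(groups)
    if df["group"].isna().any():
        raise StatsError("participants without group assignment")
    n_per_group = df.groupby("group")["participant"].nunique()
    if len(n_per_group) != 2:
        raise StatsError("exactly two groups required for weighted z-scores")
    n_total = n_per_group.sum()
    weight = df["group"].map(lambda g: n_total / (2.0 * n_per_group[g]))
    z_sum = np.zeros(len(df))
    for m in measures:
        v = df[m].to_numpy(dtype=float)
        w = weight.to_numpy(dtype=float)
        mean = np.sum(w * v) / np.sum(w)
        sd = np.sqrt(np.sum(w * (v - mean) ** 2) / np.sum(w))
        if sd <= 0 or not np.isfinite(sd):
            raise StatsError(f"zero weighted SD for measure {m!r}")
        z_sum += (v - mean) / sd
    df["z_composite"] = -z_sum
    return df


# --------------------------------------------------------------------------
# split-plot mixed ANOVA

@dataclass
class AnovaResult:
    """Tidy mixed-ANOVA table with sphericity diagnostics per within term."""

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        sel = self.table[self.table["effect"] == name]
        if sel.empty:
            raise KeyError(f"no effect {name!r}")
        return sel.iloc[0]

    def __repr__(self) -> str:
        return self.table.to_string(index=False)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis of the contrast space (orthogonal to 1)."""
    h = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, :-1]]))[0]
    return h[:, 1:]


def _gg_epsilon(sigma: np.ndarray) -> float:
    d = sigma.shape[0]
    tr = np.trace(sigma)
    if tr <= 0:
        return 1.0
    return float(tr**2 / (d * np.sum(sigma * sigma.T)))


def _mauchly(sigma: np.ndarray, n_eff: int) -> tuple[float, float]:
    """Mauchly's W and its chi-square p-value (n_eff = N - n_groups)."""
    d = sigma.shape[0]
    if d < 2:
        return 1.0, 1.0
    eig = np.linalg.eigvalsh(sigma)
    eig = np.clip(eig, 1e-300, None)
    w = float(np.exp(np.sum(np.log(eig)) - d * np.log(np.mean(eig))))
    dof = d * (d + 1) // 2 - 1
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * n_eff)
    chi2 = -n_eff * f * np.log(max(w, 1e-300))
    p = float(scipy.stats.chi2.sf(chi2, dof))
    return w, p


def mixed_anova(data: pd.DataFrame, dv: str, within, subject: str,
                between: str, gg_alpha: float = 0.05) -> AnovaResult:
    """Split-plot ANOVA: one between factor, one or two within factors.

    Requires complete within-subject data (every subject measured in every
    within cell); group sizes may differ.  Within and interaction terms are
    Greenhouse-Geisser adjusted when Mauchly's test rejects sphericity at
    `gg_alpha`; the table reports both unadjusted and adjusted p-values.
    """
    if isinstance(within, str):
        within = [within]
    within = list(within)
    df = data.copy()
    cells = [sorted(df[w].unique(), key=str) for w in within]
    for w, lv in zip(within, cells):
        df[w] = pd.Categorical(df[w], categories=lv, ordered=True)
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv,
                          observed=True)
    if wide.isna().any().any():
        raise StatsError("missing within-subject cells")
    y = wide.to_numpy()  # (N_subjects, k)
    groups = wide.index.get_level_values(between).to_numpy()
    glevels = sorted(pd.unique(groups), key=str)
    n_groups = len(glevels)
    n_sub = len(y)
    k = y.shape[1]
    if np.allclose(y.var(), 0):
        raise StatsError("dependent variable has zero variance")

    if n_groups < 2:
        raise StatsError("the between-subjects factor needs at least 2 levels")
    if n_sub - n_groups < 1:
        raise StatsError("need at least one extra subject beyond the group count")
    gidx = [np.flatnonzero(groups == g) for g in glevels]
    n_g = np.array([len(i) for i in gidx])

    rows = []

    # ---- between-subjects stratum
    m = y.mean(axis=1)  # subject means
    gm = np.array([m[i].mean() for i in gidx])
    grand = float(np.sum(n_g * gm) / n_sub)
    ss_b = k * float(np.sum(n_g * (gm - grand) ** 2))
    ss_sub = k * float(sum(np.sum((m[i] - gm[j]) ** 2) for j, i in enumerate(gidx)))
    df_b, df_sub = n_groups - 1, n_sub - n_groups
    if ss_sub > 0:
        f_b = (ss_b / df_b) / (ss_sub / df_sub)
        p_b = float(scipy.stats.f.sf(f_b, df_b, df_sub))
    else:  # zero between-subject error variance: F undefined
        f_b, p_b = np.nan, np.nan
    rows.append({"effect": between, "SS": ss_b, "SS_error": ss_sub,
                 "df1": df_b, "df2": df_sub, "F": f_b,
                 "p": p_b,
                 "np2": ss_b / (ss_b + ss_sub) if ss_b + ss_sub > 0 else 0.0,
                 "eps": np.nan,
                 "mauchly_w": np.nan, "mauchly_p": np.nan,
                 "df1_adj": df_b, "df2_adj": df_sub, "p_adj_gg": np.nan,
                 "sphericity_corrected": False})

    # ---- within strata, one per term
    c_mats = [_orthonormal_contrasts(len(lv)) for lv in cells]
    u_vecs = [np.ones(len(lv)) / np.sqrt(len(lv)) for lv in cells]
    if len(within) == 1:
        terms = [(within[0], c_mats[0])]
    else:
        terms = [
            (within[0], np.kron(c_mats[0], u_vecs[1][:, None])),
            (within[1], np.kron(u_vecs[0][:, None], c_mats[1])),
            (f"{within[0]}*{within[1]}", np.kron(c_mats[0], c_mats[1])),
        ]
    for name, C in terms:
        d = C.shape[1]
        if d == 0:  # a one-level factor contributes no contrast
            continue
        u = y @ C  # (N, d) subject scores
        ubar = u.mean(axis=0)
        ug = np.array([u[i].mean(axis=0) for i in gidx])
        ss_t = n_sub * float(np.sum(ubar**2))
        ss_gt = float(np.sum(n_g[:, None] * (ug - ubar[None, :]) ** 2))
        resid = np.vstack([u[i] - ug[j] for j, i in enumerate(gidx)])
        ss_err = float(np.sum(resid**2))
        df_t, df_gt = d, (n_groups - 1) * d
        df_err = df_sub * d
        sigma = resid.T @ resid / df_sub
        eps = _gg_epsilon(sigma)
        w, p_sph = _mauchly(sigma, df_sub)
        corrected = (d > 1) and (p_sph < gg_alpha)
        for eff, ss, dfe in ((name, ss_t, df_t),
                             (f"{between}*{name}", ss_gt, df_gt)):
            if ss_err > 0:
                f_val = (ss / dfe) / (ss_err / df_err)
                p = float(scipy.stats.f.sf(f_val, dfe, df_err))
                p_gg = float(scipy.stats.f.sf(f_val, dfe * eps, df_err * eps))
            else:  # zero within-subject error variance: F undefined
                f_val, p, p_gg = np.nan, np.nan, np.nan
            rows.append({
                "effect": eff, "SS": ss, "SS_error": ss_err,
                "df1": dfe, "df2": df_err, "F": f_val,
                "p": p_gg if corrected else p,
                "np2": ss / (ss + ss_err) if ss + ss_err > 0 else 0.0,
                "eps": eps, "mauchly_w": w, "mauchly_p": p_sph,
                "df1_adj": dfe * eps if corrected else dfe,
                "df2_adj": df_err * eps if corrected else df_err,
                "p_adj_gg": p_gg,
                "sphericity_corrected": corrected,
            })
    return AnovaResult(table=pd.DataFrame(rows))


def three_way_mixed_anova(data: pd.DataFrame, dv: str, within, subject: str,
                          between: str, **kw) -> AnovaResult:
    """Mixed ANOVA with two within-subject factors (e.g. condition x
    electrode) and one between-subjects factor."""
    if isinstance(within, str) or len(within) != 2:
        raise StatsError("three_way_mixed_anova needs exactly two within factors")
    return mixed_anova(data, dv, within, subject, between, **kw)


# --------------------------------------------------------------------------
# post-hoc tests, FDR, effect sizes, Bayes factors

@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p: float
    cohen_d: float
    p_fdr: float = np.nan
    bf10: float = np.nan


def cohen_d_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Mean difference / SD of differences."""
    diff = np.asarray(x, float) - np.asarray(y, float)
    sd = diff.std(ddof=1)
    if sd == 0:
        raise StatsError("zero variance of paired differences")
    return float(diff.mean() / sd)


def cohen_d_independent(x: np.ndarray, y: np.ndarray) -> float:
    """Mean difference / pooled SD."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if sp == 0:
        raise StatsError("zero pooled variance")
    return float((x.mean() - y.mean()) / sp)


def posthoc_tests(pairs: list[tuple], kind: str = "paired",
                  with_bayes: bool = False) -> pd.DataFrame:
    """Two-tailed t-tests over a declared family of contrasts with BH-FDR.

    `pairs` is a list of (name, x, y); `kind` is "paired" (within contrasts),
    "independent" (Welch), or "one-sample" (y ignored, tested against 0).
    """
    rows = []
    for name, x, y in pairs:
        x = np.asarray(x, float)
        if kind == "paired":
            if len(x) < 2:
                raise StatsError("need at least two pairs")
            diff = x - np.asarray(y, float)
            if np.allclose(diff, 0.0):
                # identical vectors: no effect, exactly null
                rows.append({"contrast": name, "t": 0.0, "df": len(x) - 1,
                             "p": 1.0, "cohen_d": 0.0})
                continue
            if diff.std(ddof=1) == 0:
                raise StatsError(
                    f"constant nonzero shift with zero variance in {name!r}")
            res = scipy.stats.ttest_rel(x, y)
            d = cohen_d_paired(x, y)
            df_t, n = len(x) - 1, len(x)
        elif kind == "independent":
            res = scipy.stats.ttest_ind(x, y, equal_var=False)
            d = cohen_d_independent(x, y)
            df_t, n = float(res.df), (len(x), len(y))
        elif kind == "one-sample":
            if len(x) < 2:
                raise StatsError("need at least two observations")
            res = scipy.stats.ttest_1samp(x, 0.0)
            sd = x.std(ddof=1)
            if sd == 0:
                raise StatsError("zero variance")
            d = float(x.mean() / sd)
            df_t, n = len(x) - 1, len(x)
        else:
            raise StatsError(f"unknown test kind {kind!r}")
        row = {"contrast": name, "t": float(res.statistic), "df": df_t,
               "p": float(res.pvalue), "cohen_d": d}
        if with_bayes:
            if kind == "independent":
                row["bf10"] = bayes_ttest_from_t(float(res.statistic), n[0], n[1])
            else:
                row["bf10"] = bayes_ttest_from_t(float(res.statistic), n)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    return out


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def bayes_ttest_from_t(t: float, nx: int, ny: int | None = None,
                       r: float = float(np.sqrt(2) / 2)) -> float:
    """JZS Bayes factor (BF10) for a t statistic, Cauchy prior scale r."""
    import pingouin as pg

    if ny is not None:
        return float(pg.bayesfactor_ttest(t, nx, ny, paired=False, r=r))
    return float(pg.bayesfactor_ttest(t, nx, paired=True, r=r))


def bayes_ttest(x, y=None, mu0: float = 0.0, paired: bool = True,
                r: float = float(np.sqrt(2) / 2)) -> float:
    """JZS Bayes factor for a one-sample, paired, or two-sample design."""
    x = np.asarray(x, float)
    if y is None:
        if x.std(ddof=1) == 0:
            raise StatsError("zero variance")
        t = float(scipy.stats.ttest_1samp(x, mu0).statistic)
        return bayes_ttest_from_t(t, len(x))
    y = np.asarray(y, float)
    if paired:
        diff = x - y
        if diff.std(ddof=1) == 0:
            raise StatsError("zero variance of differences")
        t = float(scipy.stats.ttest_rel(x, y).statistic)
        return bayes_ttest_from_t(t, len(x))
    t = float(scipy.stats.ttest_ind(x, y).statistic)
    return bayes_ttest_from_t(t, len(x), len(y))


def normality_homogeneity_report(data: pd.DataFrame, dv: str, within: str,
                                 between: str) -> pd.DataFrame:
    """Shapiro-Wilk per cell and Levene across groups per within level
    (reporting-only diagnostics; no automatic branching)."""
    rows = []
    for (g, w), cell in data.groupby([between, within], observed=True):
        v = cell[dv].to_numpy(dtype=float)
        sw = scipy.stats.shapiro(v) if len(v) >= 3 else None
        rows.append({"group": g, within: w, "test": "shapiro",
                     "stat": sw.statistic if sw else np.nan,
                     "p": sw.pvalue if sw else np.nan})
    for w, cell in data.groupby(within, observed=True):
        samples = [c[dv].to_numpy(dtype=float) for _, c in cell.groupby(between)]
        lv = scipy.stats.levene(*samples)
        rows.append({"group": "all", within: w, "test": "levene",
                     "stat": lv.statistic, "p": lv.pvalue})
    return pd.DataFrame(rows)
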