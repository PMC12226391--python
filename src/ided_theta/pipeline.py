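"""End-to-end orchestration: simulate or load subjects, condition the data,
extract theta summaries, and run the cohort statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import singletrial as st
from . import stats as _stats
from . import synth_eeg as se
from . import tfr as _tfr
from .data import (
    MIDFRONTAL_ELECTRODES,
    MIDLINE_ELECTRODES,
    MONTAGE_16,
    EEGRecording,
)
from .taskgen import TaskConfig, generate_sequence

DEFAULT_FREQS = np.arange(1.0, 21.0)


@dataclass
class SubjectResult:
    participant: str
    group: str
    theta: pd.DataFrame  # condition-level dB summary
    midline: pd.DataFrame  # per-electrode condition dB
    trial_theta: pd.DataFrame  # per-trial linear theta
    behaviour: pd.DataFrame
    report: dict = field(default_factory=dict)


def run_subject(rec: EEGRecording, behaviour: pd.DataFrame, participant: str,
                group: str, freqs: np.ndarray = DEFAULT_FREQS) -> SubjectResult:
    """Preprocess one recording and extract all theta summaries."""
    epochs, report = pp.preprocess_recording(
        rec, behaviour, analysis_channels=MIDFRONTAL_ELECTRODES)
    t = _tfr.morlet_power(epochs, freqs=freqs)
    baseline = _tfr.compute_baseline(t)
    avg_db = _tfr.db_normalize(_tfr.trial_average(t), baseline=baseline)
    theta = _tfr.extract_midfrontal_theta(avg_db)
    midline = _tfr.midline_profile(avg_db)
    trial_theta = _tfr.single_trial_theta(t, baseline=baseline)
    behaviour = behaviour.copy()
    for df in (theta, midline, trial_theta, behaviour):
        for col in ("group", "participant"):
            if col in df.columns:
                df.drop(columns=col, inplace=True)
        df.insert(0, "participant", participant)
        df.insert(1, "group", group)
    return SubjectResult(participant=participant, group=group, theta=theta,
                         midline=midline, trial_theta=trial_theta,
                         behaviour=behaviour, report=report)


@dataclass
class CohortResult:
    theta: pd.DataFrame
    midline: pd.DataFrame
    trial_theta: pd.DataFrame
    behaviour: pd.DataFrame

    @classmethod
    def collect(cls, subjects: list[SubjectResult]) -> "CohortResult":
        return cls(
            theta=pd.concat([s.theta for s in subjects], ignore_index=True),
            midline=pd.concat([s.midline for s in subjects], ignore_index=True),
            trial_theta=pd.concat([s.trial_theta for s in subjects],
                                  ignore_index=True),
            behaviour=pd.concat([s.behaviour for s in subjects],
                                ignore_index=True),
        )


def simulate_and_analyze_cohort(n_young: int = 20, n_older: int = 19,
                                master_seed: int = 0, fs: float = 1000.0,
                                montage=MONTAGE_16,
                                freqs: np.ndarray = DEFAULT_FREQS,
                                task_config: TaskConfig | None = None,
                                progress=None) -> CohortResult:
    """Simulate a cohort subject by subject and run the extraction pipeline.

    Memory-friendly: each subject's continuous recording is discarded after
    its epochs are summarized.
    """
    profiles = se.cohort_profiles(n_young, n_older, master_seed)
    calibrations = {
        "young": se.calibrate_profile(se.young_profile(), montage=tuple(montage)),
        "older": se.calibrate_profile(se.older_profile(), montage=tuple(montage)),
    }
    task_config = task_config or TaskConfig()
    subjects = []
    for i, profile in enumerate(profiles):
        sid = f"sub-{i + 1:02d}"
        seq = generate_sequence(task_config, seed=profile.seed)
        rec, behav = se.simulate_subject(profile, seq, fs=fs,
                                         montage=tuple(montage),
                                         calibration=calibrations[profile.group])
        subjects.append(run_subject(rec, behav, sid, profile.group, freqs=freqs))
        if progress is not None:
            progress(i + 1, len(profiles))
    return CohortResult.collect(subjects)


def behavioural_report(cohort: CohortResult) -> dict:
    """Behavioural measures, composite scores and their mixed ANOVAs."""
    groups = cohort.behaviour.groupby("participant")["group"].first()
    measures = _stats.behavioural_measures(cohort.behaviour)
    out = {}
    if groups.nunique() < 2:
        measures["group"] = measures["participant"].map(groups)
        out["scores"] = measures
        return out
    scores = _stats.performance_z(measures, groups)
    out["scores"] = scores
    if len(groups) < 3:  # too few subjects for the mixed ANOVA error strata
        return out
    for dv in ("mean_log_rt", "sd_log_rt", "error_rate", "z_composite"):
        out[f"anova_{dv}"] = _stats.mixed_anova(
            scores, dv, within="condition", subject="participant",
            between="group")
    return out


def theta_report(cohort: CohortResult, master_seed: int = 0) -> dict:
    """Theta ANOVAs, midline three-way ANOVA, and single-trial statistics."""
    out = {}
    groups = cohort.behaviour.groupby("participant")["group"].first()
    two_groups = groups.nunique() >= 2 and len(groups) >= 3
    if two_groups:
        out["anova_theta"] = _stats.mixed_anova(
            cohort.theta, "theta_db", within="condition", subject="participant",
            between="group")
        midline = cohort.midline[cohort.midline["electrode"].isin(MIDLINE_ELECTRODES)]
        out["anova_midline"] = _stats.three_way_mixed_anova(
            midline, "theta_db", within=["condition", "electrode"],
            subject="participant", between="group")
    pi = st.cohort_single_trial(
        cohort.trial_theta[["participant", "condition", "trial", "theta_raw"]],
        cohort.behaviour, master_seed=master_seed)
    pi["group"] = pi["participant"].map(groups)
    out["pi"] = pi
    if two_groups:
        out["anova_fisher_z"] = _stats.mixed_anova(
            pi[pi["valid"]], "fisher_z", within="condition",
            subject="participant", between="group")
    # one-sample tests of the Fisher z per group x condition, one FDR family
    pairs = []
    for g in sorted(pi["group"].unique()):
        for c in ("repeat", "ID", "ED"):
            cell = pi[(pi["group"] == g) & (pi["condition"] == c)]["fisher_z"]
            if len(cell) >= 2:
                pairs.append((f"{g}:{c}", cell.to_numpy(), None))
    if pairs:
        out["fisher_z_tests"] = _stats.posthoc_tests(pairs, kind="one-sample",
                                                     with_bayes=True)
    return out
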