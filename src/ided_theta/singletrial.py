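"""Robust single-trial theta-RT correlation: Shepherd's Pi with Fisher z.

Shepherd's Pi is a Spearman rank correlation computed after removing
bivariate outliers identified by *bootstrapped* Mahalanobis distances: each
point's squared Mahalanobis distance to the mean/covariance of a bootstrap
resample, averaged over resamples, so a gross outlier cannot mask itself by
inflating the covariance estimate.  Points with average squared distance at
or above the removal threshold (default 6, the published default of the
method) are discarded before the rank correlation.  Correlations are
variance-stabilized with Fisher's z-transform (atanh) for group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

DEFAULT_N_BOOT = 200
DEFAULT_THRESHOLD = 6.0


class SingleTrialError(ValueError):
    pass


@dataclass
class PiResult:
    pi: float
    n_total: int
    n_removed: int
    fisher_z: float
    removed_indices: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not -1.0 <= self.pi <= 1.0:
            raise ValueError("pi outside [-1, 1]")


def bootstrapped_mahalanobis(points: np.ndarray, n_boot: int = DEFAULT_N_BOOT,
                             rng: np.random.Generator | None = None,
                             max_retries: int = 50) -> np.ndarray:
    """Average squared Mahalanobis distance of each point over bootstrap
    resamples of the cloud.

    Each resample (with replacement) contributes the squared distance of all
    original points to the resample's mean and covariance; degenerate
    resamples (singular covariance) are redrawn a bounded number of times.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise SingleTrialError("points must be an (n, 2) array")
    n = len(points)
    if n < 4:
        raise SingleTrialError("need at least 4 points")
    if not np.all(np.isfinite(points)):
        raise SingleTrialError("points must be finite")
    rng = rng or np.random.default_rng()
    total = np.zeros(n)
    done = 0
    for _ in range(max_retries):
        need = n_boot - done
        idx = rng.integers(0, n, size=(need, n))
        sample = points[idx]  # (need, n, 2)
        mu = sample.mean(axis=1)
        centred = sample - mu[:, None, :]
        cov = np.einsum("bni,bnj->bij", centred, centred) / (n - 1)
        det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] * cov[:, 1, 0]
        scale = (0.5 * (cov[:, 0, 0] + cov[:, 1, 1]) + 1e-30) ** 2
        ok = np.isfinite(det) & (det > 1e-12 * scale)
        if not ok.any():
            continue
        cov, det = cov[ok], det[ok]
        # analytic 2x2 inverse
        inv = np.empty_like(cov)
        inv[:, 0, 0] = cov[:, 1, 1]
        inv[:, 1, 1] = cov[:, 0, 0]
        inv[:, 0, 1] = -cov[:, 0, 1]
        inv[:, 1, 0] = -cov[:, 1, 0]
        inv /= det[:, None, None]
        diff = points[None, :, :] - mu[ok][:, None, :]  # (b, n, 2)
        d2 = np.einsum("bni,bij,bnj->bn", diff, inv, diff)
        total += d2.sum(axis=0)
        done += int(ok.sum())
        if done >= n_boot:
            break
    else:
        raise SingleTrialError("covariance degenerate in bootstrap resamples")
    return total / done


def shepherds_pi(x: np.ndarray, y: np.ndarray, n_boot: int = DEFAULT_N_BOOT,
                 threshold: float = DEFAULT_THRESHOLD,
                 rng: np.random.Generator | None = None) -> PiResult:
    """Spearman correlation of (x, y) after bootstrapped-Mahalanobis outlier
    removal.  Fewer than 3 retained points yields an invalid result."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SingleTrialError("x and y must be equal-length 1-d arrays")
    pts = np.column_stack([x, y])
    d2 = bootstrapped_mahalanobis(pts, n_boot=n_boot, rng=rng)
    keep = d2 < threshold
    removed = np.flatnonzero(~keep)
    if keep.sum() < 3:
        return PiResult(pi=np.nan, n_total=len(x), n_removed=len(removed),
                        fisher_z=np.nan, removed_indices=removed, valid=False)
    pi = float(spearmanr(x[keep], y[keep]).statistic)
    return PiResult(pi=pi, n_total=len(x), n_removed=len(removed),
                    fisher_z=fisher_z(pi) if abs(pi) < 1 else np.sign(pi) * np.inf,
                    removed_indices=removed)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, z = atanh(r)."""
    if not -1.0 < r < 1.0:
        raise SingleTrialError("|r| must be < 1 for the Fisher transform")
    return float(np.arctanh(r))


def cohort_single_trial(theta: pd.DataFrame, behaviour: pd.DataFrame,
                        n_boot: int = DEFAULT_N_BOOT,
                        threshold: float = DEFAULT_THRESHOLD,
                        log_rt: bool = True, master_seed: int = 0) -> pd.DataFrame:
    """Shepherd's Pi per participant x condition across a cohort.

    `theta` holds per-trial midfrontal theta (participant, condition, trial,
    theta_raw); `behaviour` the matching trial table with rt_ms and correct.
    Only correct trials enter.  RTs enter on the natural-log scale by
    default, mirroring the behavioural analyses.  Bootstrap seeds derive
    deterministically from `master_seed` per participant x condition.
    """
    theta = theta.drop(columns=[c for c in ("rt_ms", "correct") if c in theta.columns])
    merged = theta.merge(
        behaviour[["participant", "trial", "rt_ms", "correct"]],
        on=["participant", "trial"], how="left",
    )
    if merged["correct"].isna().any():
        bad = merged.loc[merged["correct"].isna(), ["participant", "trial"]]
        raise SingleTrialError(
            f"trials without behavioural match:\n{bad.to_string(index=False)}")
    merged = merged[merged["correct"].astype(bool) & merged["rt_ms"].notna()]
    rows = []
    participants = sorted(merged["participant"].unique())
    for p_i, participant in enumerate(participants):
        for c_i, condition in enumerate(("repeat", "ID", "ED")):
            cell = merged[(merged["participant"] == participant)
                          & (merged["condition"] == condition)]
            if len(cell) < 4:
                continue
            rt = cell["rt_ms"].to_numpy()
            rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, p_i, c_i]))
            res = shepherds_pi(cell["theta_raw"].to_numpy(),
                               np.log(rt) if log_rt else rt,
                               n_boot=n_boot, threshold=threshold, rng=rng)
            rows.append({
                "participant": participant,
                "condition": condition,
                "n": len(cell),
                "pi": res.pi,
                "fisher_z": res.fisher_z,
                "n_removed": res.n_removed,
                "valid": res.valid,
            })
    return pd.DataFrame(rows)
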