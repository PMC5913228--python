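"""Group-level statistics, ROI extraction, small-volume correction, behavior curves.

Subject-level effects (betas, contrast values, map voxels) are tested
with standard one-sample/paired t-tests and Pearson correlations.
Map-level multiple comparisons are controlled within an ROI by
Bonferroni correction across its voxels — conservative and
simulation-testable, in place of random-field family-wise control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import IREV, SessionSchedule


@dataclass
class GroupResult:
    statistic_name: str
    statistic: float
    p: float
    dof: int
    values: np.ndarray
    alternative: str = "two-sided"


def _check_values(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError(f"{name} needs n >= 3, got {values.size}")
    if np.std(values, ddof=1) == 0:
        raise ValueError(f"{name}: zero variance in inputs")
    return values


def one_sample_t(values: np.ndarray, popmean: float = 0.0, alternative: str = "two-sided") -> GroupResult:
    """One-sample t-test of subject values against ``popmean``."""
    values = _check_values(values, "one_sample_t")
    res = stats.ttest_1samp(values, popmean, alternative=alternative)
    return GroupResult("t", float(res.statistic), float(res.pvalue), values.size - 1, values,
                       alternative)


def paired_t(values_a: np.ndarray, values_b: np.ndarray, alternative: str = "two-sided") -> GroupResult:
    """Paired t-test between two aligned subject-value vectors."""
    a, b = np.asarray(values_a, dtype=float), np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must be aligned")
    diff = _check_values(a - b, "paired_t")
    res = stats.ttest_rel(a, b, alternative=alternative)
    return GroupResult("t", float(res.statistic), float(res.pvalue), diff.size - 1, diff,
                       alternative)


def across_subject_correlation(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> GroupResult:
    """Pearson correlation of two subject-level measures."""
    x = _check_values(x, "correlation x")
    y = _check_values(y, "correlation y")
    if x.shape != y.shape:
        raise ValueError("correlation inputs must be aligned")
    res = stats.pearsonr(x, y, alternative=alternative)
    return GroupResult("r", float(res.statistic), float(res.pvalue), x.size - 2,
                       np.column_stack([x, y]), alternative)


def roi_mean(volume: np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean map value over in-ROI voxels (NaN voxels ignored)."""
    if volume.shape != roi_mask.shape:
        raise ValueError("volume and mask shapes differ")
    vals = volume[roi_mask.astype(bool)]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("empty volume/ROI intersection")
    return float(vals.mean())


def group_map_ttest(subject_maps: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t-test across subject maps: (t_map, p_map).

    Voxels defined in fewer than three subjects (e.g. skipped searchlight
    centers at the mask edge) come back NaN.
    """
    import warnings

    stack = np.stack(subject_maps)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy small-sample notices on all-NaN voxels
        res = stats.ttest_1samp(stack, 0.0, axis=0, nan_policy="omit")
    t_map = np.asarray(res.statistic, dtype=float)
    p_map = np.asarray(res.pvalue, dtype=float)
    too_few = np.sum(~np.isnan(stack), axis=0) < 3
    t_map[too_few] = np.nan
    p_map[too_few] = np.nan
    return t_map, p_map


def small_volume_correct(
    p_map: np.ndarray, roi_mask: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni control across the ROI's voxels.

    Returns (survivor mask, corrected-p map): corrected p = p * n tested
    voxels (capped at 1) inside the ROI, NaN elsewhere; survivors are
    in-ROI voxels with corrected p < alpha.
    """
    if p_map.shape != roi_mask.shape:
        raise ValueError("p map and ROI mask shapes differ")
    roi = roi_mask.astype(bool) & ~np.isnan(p_map)
    n = int(roi.sum())
    corrected = np.full(p_map.shape, np.nan)
    if n:
        corrected[roi] = np.minimum(p_map[roi] * n, 1.0)
    survivors = np.zeros_like(roi)
    if n:
        survivors[roi] = corrected[roi] < alpha
    return survivors, corrected


def choice_reversal_curves(
    choices_per_subject: list[np.ndarray],
    schedules_per_subject: list[list[SessionSchedule]],
    window: int = 3,
) -> pd.DataFrame:
    """Proportion of high-intensity-CS free choices around reversals.

    Positions are indexed by free-choice order (-window..-1 before,
    1..window after each reversal), with "high-intensity CS" defined by
    the state in force on each plotted trial (so a value reversal shows
    the classic drop at +1 followed by relearning, while identity
    reversals leave the curve high).  Returns a tidy table (subject,
    reversal_kind, position, prop_high) averaged within subject and
    reversal type; positions without any free trial are absent for that
    subject/reversal (reported missing).
    """
    rows = []
    for subj, (choices, schedules) in enumerate(zip(choices_per_subject, schedules_per_subject)):
        per = {}  # (kind, position) -> list of 0/1
        offset = 0
        for sched in schedules:
            df = sched.to_frame()
            free_idx = df.index[df["choice_type"] == "free"].to_numpy()
            for rev in sched.reversals:
                t0 = rev["trial_index"]
                before = free_idx[free_idx < t0][-window:]
                after = free_idx[free_idx >= t0][:window]
                for k, t in enumerate(reversed(before)):
                    c = choices[offset + t]
                    if c >= 0:
                        hit = int(c == int(df.loc[t, "high_cs"]))
                        per.setdefault((rev["kind"], -(k + 1)), []).append(hit)
                for k, t in enumerate(after):
                    c = choices[offset + t]
                    if c >= 0:
                        hit = int(c == int(df.loc[t, "high_cs"]))
                        per.setdefault((rev["kind"], k + 1), []).append(hit)
            offset += sched.n_trials
        for (kind, pos), vals in sorted(per.items()):
            rows.append(
                {"subject": subj, "reversal_kind": kind, "position": pos,
                 "prop_high": float(np.mean(vals)), "n_trials": len(vals)}
            )
    return pd.DataFrame(rows)


def condition_table(curves: pd.DataFrame) -> pd.DataFrame:
    """Wide subject x (reversal_kind, position) table for external ANOVA tools."""
    return curves.pivot_table(index="subject", columns=["reversal_kind", "position"],
                              values="prop_high")
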