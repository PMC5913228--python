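"""Searchlight template-correlation MVPA of task-state expectations.

For each searchlight sphere, CS-evoked activity patterns from two runs
define one "template" per task state (forced-choice trials only,
averaged over the two occurrences of each state per run, with the
per-voxel mean across the four states removed).  Each trial's pattern in
the left-out run is Pearson-correlated with the four templates, the
correlations are Fisher z-transformed and sorted by the relation between
the trial's state and each template's state (SISV / SIDV / DISV /
DIDV).  Trial-averaged z values are mapped to the sphere center,
yielding one map per relation label for group contrasts such as
SISV - DISV (identity coding) or SISV - SIDV (CS-value coding).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from . import glm_fir
from .synthetic_data import SubjectDataset
from .task_design import StateRelation, enumerate_states, state_relation

R_CLIP = 1.0 - 1e-7
MIN_SPHERE_VOXELS = 10
LABELS = [rel.value for rel in StateRelation]


def fisher_z(r, clip: bool = True):
    """Fisher's z = (ln(1+r) - ln(1-r)) / 2; |r| = 1 raises unless clipped."""
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -R_CLIP, R_CLIP)
    elif np.any(np.abs(r) >= 1):
        raise ValueError("|r| >= 1; enable clipping or pass r in (-1, 1)")
    out = 0.5 * (np.log1p(r) - np.log1p(-r))
    return float(out) if out.ndim == 0 else out


def build_templates(patterns: np.ndarray, state_ids: np.ndarray) -> np.ndarray:
    """State templates from per-occurrence patterns.

    ``patterns`` is (n_patterns, n_vox) with one row per state occurrence
    (both template runs pooled); ``state_ids`` labels each row 0..3.
    Rows of the result follow canonical state order.  After averaging
    within state, the per-voxel mean across the four templates is
    subtracted, so templates sum to zero at every voxel.
    """
    patterns = np.asarray(patterns, dtype=float)
    state_ids = np.asarray(state_ids)
    templates = np.empty((4, patterns.shape[1]))
    for s in range(4):
        rows = patterns[state_ids == s]
        if rows.shape[0] == 0:
            raise ValueError(f"no template pattern for state {s}")
        templates[s] = rows.mean(axis=0)
    return templates - templates.mean(axis=0, keepdims=True)


def trial_similarity(test_pattern: np.ndarray, templates: np.ndarray, trial_state_id: int) -> dict:
    """Fisher-z correlation of one test pattern with the four state templates.

    Returns ``{"z_state": (4,) array in canonical state order, "labels":
    relation label per template, "by_label": dict label -> z}``.  A
    zero-variance test pattern raises (callers flag and exclude the trial).
    """
    test_pattern = np.asarray(test_pattern, dtype=float)
    if np.std(test_pattern) == 0:
        raise ValueError("zero-variance test pattern")
    states = enumerate_states()
    z = np.empty(4)
    for s in range(4):
        t = templates[s]
        if np.std(t) == 0:
            z[s] = 0.0
        else:
            z[s] = fisher_z(np.corrcoef(test_pattern, t)[0, 1])
    labels = [state_relation(states[trial_state_id], states[s]).value for s in range(4)]
    return {"z_state": z, "labels": labels, "by_label": dict(zip(labels, z))}


# ---------------------------------------------------------------------------
# pattern estimation from BOLD via the event GLMs
# ---------------------------------------------------------------------------


def _template_events(trace: pd.DataFrame, timing: pd.DataFrame) -> list[dict]:
    """Template-GLM events: forced and free trials grouped by state occurrence,
    plus US and rating regressors."""
    events = []
    occ: dict[int, int] = {}
    block_occ: dict[int, tuple[int, int]] = {}
    for _, row in trace.iterrows():
        b = int(row["block"])
        if b not in block_occ:
            s = int(row["state_id"])
            occ[s] = occ.get(s, -1) + 1
            block_occ[b] = (s, occ[s])
    for t, row in trace.iterrows():
        s, k = block_occ[int(row["block"])]
        kind = "forced" if row["choice_type"] == "forced" else "free"
        events.append(
            {
                "onset": timing["onset_cue"].iloc[t],
                "duration": timing["onset_choice"].iloc[t] - timing["onset_cue"].iloc[t],
                "name": f"{kind}_state{s}_occ{k}",
            }
        )
    responded = timing["responded"].to_numpy() == 1
    for o in timing.loc[responded, "onset_us"]:
        events.append({"onset": o, "duration": 0.0, "name": "us"})
    for o in timing.loc[responded, "onset_rating"]:
        events.append({"onset": o, "duration": 0.0, "name": "rating"})
    return events


def _test_events(trace: pd.DataFrame, timing: pd.DataFrame) -> list[dict]:
    events = [
        {
            "onset": timing["onset_cue"].iloc[t],
            "duration": timing["onset_choice"].iloc[t] - timing["onset_cue"].iloc[t],
            "name": f"trial_{t:03d}",
        }
        for t in range(len(trace))
    ]
    responded = timing["responded"].to_numpy() == 1
    for o in timing.loc[responded, "onset_us"]:
        events.append({"onset": o, "duration": 0.0, "name": "us"})
    for o in timing.loc[responded, "onset_rating"]:
        events.append({"onset": o, "duration": 0.0, "name": "rating"})
    return events


def estimate_run_patterns(dataset: SubjectDataset, run: int, voxels: np.ndarray) -> dict:
    """Template and single-trial CS-evoked patterns for one run.

    ``voxels`` is an (n_vox, 3) integer array of grid coordinates.
    Returns ``template_patterns`` (n_occurrence_patterns, n_vox) with
    ``template_states``, and ``trial_patterns`` (n_trials, n_vox) from
    the single-trial GLM.
    """
    trace = dataset.run_trace(run)
    timing = dataset.onsets[run]
    bold = dataset.bold[run]
    series = bold[voxels[:, 0], voxels[:, 1], voxels[:, 2], :]
    n_scans = series.shape[1]
    nuis = dataset.nuisance[run]

    tdesign = glm_fir.build_event_design(_template_events(trace, timing), n_scans, tr=dataset.tr,
                                         nuisance=nuis)
    tfit = glm_fir.fit_ols(series, tdesign)
    tpatterns, tstates = [], []
    for s in range(4):
        for k in range(2):
            cols = tdesign.column_index(kind="event", name=f"forced_state{s}_occ{k}")
            if cols:
                tpatterns.append(tfit.betas[cols[0]])
                tstates.append(s)
    sdesign = glm_fir.build_event_design(_test_events(trace, timing), n_scans, tr=dataset.tr,
                                         nuisance=nuis)
    sfit = glm_fir.fit_ols(series, sdesign)
    trial_patterns = np.empty((len(trace), series.shape[0]))
    for t in range(len(trace)):
        col = sdesign.column_index(kind="event", name=f"trial_{t:03d}")[0]
        trial_patterns[t] = sfit.betas[col]
    return {
        "template_patterns": np.asarray(tpatterns),
        "template_states": np.asarray(tstates),
        "trial_patterns": trial_patterns,
    }


def _zscore_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    out = np.zeros_like(m)
    out[ok] = (m[ok] - mu[ok]) / sd[ok]
    return out, ok


def _fold_similarities(
    test_patterns: np.ndarray,
    templates: np.ndarray,
    idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z correlations (n_trials, 4) over the voxel subset ``idx``."""
    B, ok_b = _zscore_rows(test_patterns[:, idx])
    T, _ = _zscore_rows(templates[:, idx])
    r = (B @ T.T) / idx.shape[0]
    z = fisher_z(r)
    return z, ok_b


def sphere_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


class SearchlightResult(dict):
    """Maps relation label -> 3-D mean-z map; extras under ``meta``."""

    def __init__(self, maps: dict, skipped: list, n_trials: int):
        super().__init__(maps)
        self.meta = {"skipped_centers": skipped, "n_trials": n_trials}


def searchlight_run(
    dataset: SubjectDataset,
    radius: float = 3.0,
    mask: np.ndarray | None = None,
    test_trials: str = "forced",
) -> SearchlightResult:
    """Leave-one-run-out searchlight over the in-brain mask.

    Each of the subject's runs serves once as the test run, with
    templates built from the other runs' forced-choice state patterns.
    Per-label z values are averaged over all test trials of all folds
    and assigned to the sphere center.  Spheres with fewer than
    ``MIN_SPHERE_VOXELS`` in-mask voxels are skipped and logged.
    """
    if mask is None:
        mask = dataset.masks["brain"]
    if len(dataset.bold) < 2:
        raise ValueError("searchlight needs at least two runs for leave-one-run-out folds")
    voxels = np.argwhere(mask)
    flat = {tuple(v): i for i, v in enumerate(voxels)}
    n_runs = len(dataset.bold)
    runs = [estimate_run_patterns(dataset, r, voxels) for r in range(n_runs)]

    sums = {lab: np.zeros(voxels.shape[0]) for lab in LABELS}
    counts = {lab: np.zeros(voxels.shape[0]) for lab in LABELS}
    offsets = sphere_offsets(radius)
    spheres: list[np.ndarray] = []
    skipped: list[tuple[int, int, int]] = []
    for i, v in enumerate(voxels):
        coords = v + offsets
        idx = [flat[tuple(c)] for c in coords if tuple(c) in flat]
        arr = np.asarray(idx)
        if arr.shape[0] < MIN_SPHERE_VOXELS:
            skipped.append(tuple(int(x) for x in v))
            spheres.append(None)
        else:
            spheres.append(arr)

    states = enumerate_states()
    total_trials = 0
    for test_run in range(n_runs):
        template_runs = [r for r in range(n_runs) if r != test_run]
        tp = np.concatenate([runs[r]["template_patterns"] for r in template_runs])
        ts = np.concatenate([runs[r]["template_states"] for r in template_runs])
        templates = build_templates(tp, ts)
        trace = dataset.run_trace(test_run)
        keep = trace["responded"].to_numpy() == 1
        if test_trials == "forced":
            keep &= trace["choice_type"].to_numpy() == "forced"
        trial_patterns = runs[test_run]["trial_patterns"][keep]
        trial_states = trace.loc[keep, "state_id"].to_numpy()
        total_trials += int(keep.sum())
        # relation label of template s for each kept trial
        label_mat = np.array(
            [[state_relation(states[st], states[s]).value for s in range(4)] for st in trial_states]
        )
        for i, idx in enumerate(spheres):
            if idx is None:
                continue
            z, ok = _fold_similarities(trial_patterns, templates, idx)
            for s in range(4):
                for lab in LABELS:
                    sel = ok & (label_mat[:, s] == lab)
                    sums[lab][i] += z[sel, s].sum()
                    counts[lab][i] += sel.sum()

    maps = {}
    for lab in LABELS:
        vol = np.full(mask.shape, np.nan)
        with np.errstate(invalid="ignore"):
            vals = sums[lab] / counts[lab]
        vol[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = vals
        maps[lab] = vol
    return SearchlightResult(maps, skipped, total_trials)


def label_contrast(maps: dict, a: str, b: str) -> np.ndarray:
    """Voxelwise difference map a - b between two relation-label maps."""
    if a not in maps or b not in maps:
        raise ValueError(f"labels {a!r}/{b!r} not present in maps")
    ma, mb = np.asarray(maps[a]), np.asarray(maps[b])
    if ma.shape != mb.shape:
        raise ValueError("label maps have mismatched shapes")
    return ma - mb


def roi_similarity_table(
    dataset: SubjectDataset, roi_voxels: np.ndarray, test_trials: str = "forced"
) -> pd.DataFrame:
    """Per-trial template correlations within one ROI voxel set.

    Leave-one-run-out as in the searchlight, but at a single fixed voxel
    set (e.g. a sphere around the identity-coding OFC peak).  Returns one
    row per kept trial with run, trial, state_id, ``z_state_{0..3}`` in
    canonical state order, and per-relation-label columns.
    """
    n_runs = len(dataset.bold)
    if n_runs < 2:
        raise ValueError("template correlation needs at least two runs for leave-one-run-out folds")
    runs = [estimate_run_patterns(dataset, r, roi_voxels) for r in range(n_runs)]
    states = enumerate_states()
    rows = []
    for test_run in range(n_runs):
        template_runs = [r for r in range(n_runs) if r != test_run]
        tp = np.concatenate([runs[r]["template_patterns"] for r in template_runs])
        ts = np.concatenate([runs[r]["template_states"] for r in template_runs])
        templates = build_templates(tp, ts)
        trace = dataset.run_trace(test_run)
        keep = trace["responded"].to_numpy() == 1
        if test_trials == "forced":
            keep &= trace["choice_type"].to_numpy() == "forced"
        idx = np.arange(roi_voxels.shape[0])
        z, ok = _fold_similarities(runs[test_run]["trial_patterns"][keep], templates, idx)
        for i, (t, row) in enumerate(trace[keep].iterrows()):
            if not ok[i]:
                continue
            rec = {
                "run": test_run,
                "trial": int(row["trial"]),
                "block": int(row["block"]),
                "state_id": int(row["state_id"]),
            }
            for s in range(4):
                rec[f"z_state_{s}"] = z[i, s]
                rel = state_relation(states[int(row["state_id"])], states[s]).value
                rec[f"z_{rel}"] = z[i, s]
            rows.append(rec)
    return pd.DataFrame(rows).sort_values(["run", "trial"]).reset_index(drop=True)


def fold_pairs(n_runs: int) -> list[tuple[int, ...]]:
    """Unordered template-run pairs; exposed for fold-symmetry checks."""
    return list(combinations(range(n_runs), n_runs - 1))
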