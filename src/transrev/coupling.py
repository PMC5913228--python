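"""Linking midbrain prediction-error responses to OFC identity-expectation updates.

From the per-trial template correlations at an OFC sphere, an identity
information trace is computed (mean z over the two sweet-state templates
minus mean z over the two savory-state templates), and its absolute
trial-to-trial change quantifies how strongly the expressed identity
expectation moved.  Two complementary analyses relate that update to the
midbrain:

* trial level — the update from trial t to t+1 modulates the US-evoked
  FIR response on trial t (free-choice deliveries in a separate
  regressor); a positive bin-3-5 midbrain beta means bigger error
  responses co-occur with bigger next-trial expectation shifts;
* subject level — the mean pre-to-post identity-reversal change in the
  (post-state-referenced) information trace is correlated across
  subjects with the midbrain |iPE| response.

A directional control splits |iPE| by the direction of the most recent
identity reversal (sweet-to-savory vs savory-to-sweet): value-neutral
identity errors predict positively correlated responses to the two
directions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import glm_fir
from .synthetic_data import SubjectDataset
from .task_design import IREV, SWEET

SWEET_STATES = (0, 1)
SAVORY_STATES = (2, 3)
MIN_UPDATE_TRIALS = 10


def identity_information_trace(similarities: pd.DataFrame) -> pd.DataFrame:
    """Identity information and its trial-to-trial update from a similarity table.

    ``similarities`` is the per-trial table from
    :func:`transrev.pattern_analysis.roi_similarity_table` (forced-choice
    trials).  ``info`` is sweet-minus-savory mean template z; ``update``
    on row t is |info(next) - info(t)| within the same run and is NaN on
    each run's last entry (no next trial exists across the boundary).
    """
    req = [f"z_state_{s}" for s in range(4)]
    missing = [c for c in req if c not in similarities.columns]
    if missing:
        raise ValueError(f"similarity table lacks columns {missing}")
    out = similarities[["run", "trial", "block", "state_id"]].copy()
    z_sweet = similarities[[f"z_state_{s}" for s in SWEET_STATES]].mean(axis=1)
    z_savory = similarities[[f"z_state_{s}" for s in SAVORY_STATES]].mean(axis=1)
    out["info"] = (z_sweet - z_savory).to_numpy()
    update = np.full(len(out), np.nan)
    info = out["info"].to_numpy()
    runs = out["run"].to_numpy()
    for i in range(len(out) - 1):
        if runs[i + 1] == runs[i]:
            update[i] = abs(info[i + 1] - info[i])
    out["update"] = update
    return out


def _roi_voxels(dataset: SubjectDataset, roi: str) -> np.ndarray:
    return np.argwhere(dataset.masks[roi])


def update_modulated_glm(
    dataset: SubjectDataset,
    info_trace: pd.DataFrame,
    roi: str = "midbrain",
    bins: tuple[int, ...] = glm_fir.PEAK_BINS_DEFAULT,
) -> float:
    """Per-subject coupling beta: OFC-update-modulated US response in an ROI.

    For each run, the US-evoked FIR response on forced-choice trials is
    modulated by the update value assigned to that trial; free-choice
    deliveries get their own unmodulated FIR set.  The three RL
    prediction-error modulators ride along as covariates, so the update
    beta quantifies US-evoked variance related to the next-trial
    expectation shift *beyond* the deterministic PE response (both the
    update trace and the PE response are reversal-locked, so omitting
    the covariates would manufacture coupling out of shared task
    structure).  The update modulator is z-scored within run, putting
    the beta on a response-per-SD scale.  Returns the ROI-mean of the
    bin-averaged update beta, averaged across runs.  Raises if fewer
    than ``MIN_UPDATE_TRIALS`` trials carry a defined update.
    """
    if int(info_trace["update"].notna().sum()) < MIN_UPDATE_TRIALS:
        raise ValueError(
            f"only {int(info_trace['update'].notna().sum())} valid update trials; "
            f"need >= {MIN_UPDATE_TRIALS}"
        )
    vox = _roi_voxels(dataset, roi)
    betas = []
    for run in range(len(dataset.bold)):
        trace = dataset.run_trace(run)
        timing = dataset.onsets[run]
        responded = timing["responded"].to_numpy() == 1
        forced = (trace["choice_type"].to_numpy() == "forced") & responded
        free = (trace["choice_type"].to_numpy() == "free") & responded
        upd = info_trace[info_trace["run"] == run].set_index("trial")["update"]
        mod = np.array([upd.get(t, np.nan) for t in trace.loc[forced, "trial"]])
        if np.isnan(mod).all() or np.nanstd(mod) == 0:
            continue
        mod = (mod - np.nanmean(mod)) / np.nanstd(mod)
        onsets_forced = timing.loc[forced, "onset_us"].to_numpy()
        onsets_free = timing.loc[free, "onset_us"].to_numpy()
        extra = {"us_free": onsets_free} if onsets_free.size else None
        mods = {"update": mod}
        for cov in ("abs_iPE", "vPE_pos", "vPE_neg"):
            mods[cov] = trace.loc[forced, cov].to_numpy()
        design = glm_fir.build_fir_design(
            onsets_forced,
            mods,
            n_scans=dataset.bold[run].shape[-1],
            tr=dataset.tr,
            nuisance=dataset.nuisance[run],
            event_name="us_forced",
            extra_event_sets=extra,
        )
        series = dataset.bold[run][vox[:, 0], vox[:, 1], vox[:, 2], :]
        fit = glm_fir.fit_ols(series, design)
        eff = glm_fir.bin_average_contrast(fit, "update", bins=bins, event_name="us_forced")
        betas.append(float(np.nanmean(eff)))
    if not betas:
        raise ValueError("no run yielded a defined update modulator")
    return float(np.mean(betas))


def pe_modulated_betas(
    dataset: SubjectDataset,
    roi: str = "midbrain",
    modulators: tuple[str, ...] = ("abs_iPE", "vPE_pos", "vPE_neg"),
    bins: tuple[int, ...] = glm_fir.PEAK_BINS_DEFAULT,
) -> dict[str, float]:
    """ROI-mean bin-averaged FIR betas for the RL prediction-error modulators.

    The univariate engine applied at an ROI: US-locked FIR over all
    responded trials, the unsigned iPE and the split value PE as
    modulators, sniff/rating traces as nuisance.  Betas are averaged
    across runs.
    """
    vox = _roi_voxels(dataset, roi)
    acc = {m: [] for m in modulators}
    for run in range(len(dataset.bold)):
        trace = dataset.run_trace(run)
        timing = dataset.onsets[run]
        responded = timing["responded"].to_numpy() == 1
        mods = {m: trace.loc[responded, m].to_numpy() for m in modulators}
        design = glm_fir.build_fir_design(
            timing.loc[responded, "onset_us"].to_numpy(),
            mods,
            n_scans=dataset.bold[run].shape[-1],
            tr=dataset.tr,
            nuisance=dataset.nuisance[run],
        )
        series = dataset.bold[run][vox[:, 0], vox[:, 1], vox[:, 2], :]
        fit = glm_fir.fit_ols(series, design)
        for m in modulators:
            acc[m].append(float(np.nanmean(glm_fir.bin_average_contrast(fit, m, bins=bins))))
    return {m: float(np.mean(v)) for m, v in acc.items()}


def reversal_update_summary(
    info_trace: pd.DataFrame, dataset: SubjectDataset, offset: int = 1
) -> float:
    """Mean pre-to-post change in post-state-referenced identity information.

    For every identity reversal at trial t0, the information trace is
    re-referenced to the post-reversal identity (positive = expressing
    the post-reversal identity) and the value ``offset`` forced trials
    after t0 (strictly later than t0, i.e. after at least one US of the
    new block has been experienced) is compared with the value
    ``offset`` forced trials before t0.  Reversals too close to a run
    edge are skipped.
    """
    changes = []
    for run, sched in enumerate(dataset.schedules):
        sub = info_trace[info_trace["run"] == run].reset_index(drop=True)
        if sub.empty:
            continue
        trials = sub["trial"].to_numpy()
        info = sub["info"].to_numpy()
        states = {t.index: t.state for t in sched.trials}
        for rev in sched.reversals:
            if rev["kind"] != IREV:
                continue
            t0 = rev["trial_index"]
            post_sign = 1.0 if states[t0].identity == SWEET else -1.0
            pre_idx = np.where(trials < t0)[0]
            post_idx = np.where(trials > t0)[0]
            if pre_idx.size < offset or post_idx.size < offset:
                continue  # reversal at a run edge
            pre = info[pre_idx[-offset]]
            post = info[post_idx[offset - 1]]
            changes.append(post_sign * (post - pre))
    return float(np.mean(changes)) if changes else 0.0


def _reversal_directions(trace: pd.DataFrame) -> np.ndarray:
    """Per-trial direction of the most recent identity transition.

    Returns an object array of ``"sw_sv"`` / ``"sv_sw"`` / ``None`` (no
    identity reversal yet in this run).
    """
    out = np.full(len(trace), None, dtype=object)
    current = None
    prev_block = None
    prev_identity = None
    for i, row in trace.iterrows():
        if prev_block is None:
            pass
        elif row["block"] != prev_block and row["identity"] != prev_identity:
            current = "sw_sv" if prev_identity == SWEET else "sv_sw"
        prev_block, prev_identity = row["block"], row["identity"]
        out[i] = current
    return out


def directional_ipe_betas(
    dataset: SubjectDataset,
    roi: str = "midbrain",
    bins: tuple[int, ...] = glm_fir.PEAK_BINS_DEFAULT,
) -> dict[str, float]:
    """Midbrain |iPE| betas split by identity-reversal direction.

    US trials are assigned to the direction of the most recent identity
    reversal in their run (sweet-to-savory or savory-to-sweet); each
    direction gets its own FIR set with an |iPE| modulator, and trials
    preceding the first identity reversal form an unmodulated set.
    Returns ``{"sw_sv": beta, "sv_sw": beta}``; a direction absent from
    the data comes back as NaN.
    """
    vox = _roi_voxels(dataset, roi)
    acc = {"sw_sv": [], "sv_sw": []}
    for run in range(len(dataset.bold)):
        trace = dataset.run_trace(run)
        timing = dataset.onsets[run]
        responded = timing["responded"].to_numpy() == 1
        direction = _reversal_directions(trace)
        onsets = timing["onset_us"].to_numpy()
        abs_ipe = trace["abs_iPE"].to_numpy()
        sets: dict = {}
        primary = None
        for key in ("sw_sv", "sv_sw"):
            sel = responded & (direction == key)
            if sel.sum() == 0:
                continue
            spec = (onsets[sel], {"abs_iPE": abs_ipe[sel]})
            if primary is None:
                primary = (key, spec)
            else:
                sets[f"us_{key}"] = spec
        rest = responded & (direction == None)  # noqa: E711  (elementwise object compare)
        if rest.sum():
            sets["us_rest"] = onsets[rest]
        if primary is None:
            continue
        design = glm_fir.build_fir_design(
            primary[1][0],
            primary[1][1],
            n_scans=dataset.bold[run].shape[-1],
            tr=dataset.tr,
            nuisance=dataset.nuisance[run],
            event_name=f"us_{primary[0]}",
            extra_event_sets=sets or None,
        )
        series = dataset.bold[run][vox[:, 0], vox[:, 1], vox[:, 2], :]
        fit = glm_fir.fit_ols(series, design)
        for key in ("sw_sv", "sv_sw"):
            cols = design.column_index(kind="fir", name=f"us_{key}", modulator="abs_iPE")
            if cols:
                acc[key].append(
                    float(
                        np.nanmean(
                            glm_fir.bin_average_contrast(
                                fit, "abs_iPE", bins=bins, event_name=f"us_{key}"
                            )
                        )
                    )
                )
    return {k: (float(np.mean(v)) if v else float("nan")) for k, v in acc.items()}
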