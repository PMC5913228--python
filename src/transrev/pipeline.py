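"""End-to-end pipeline: simulate -> fit -> GLM -> MVPA -> coupling -> group.

``run_pipeline`` drives the whole analysis on a synthetic cohort and
writes its artifacts (events tables, fit results, group statistics) to
an output directory.  The configuration is schema-validated and fully
serialisable; outputs are reproducible from config + seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import coupling, group_inference, io, model_fitting, pattern_analysis, rl_model
from .synthetic_data import SyntheticConfig, generate_cohort

log = logging.getLogger("transrev")


class PipelineConfig(BaseModel):
    """All stage configurations plus the global seed and scale choices."""

    model_config = ConfigDict(extra="forbid")

    synth: SyntheticConfig = SyntheticConfig()
    seed: int = 0
    c_max: float = 5.0
    fit_restarts: int = 3
    searchlight: bool = False  # full searchlight maps are opt-in (ROI analyses always run)
    searchlight_radius: float = 3.0
    mvpa_test_trials: str = "forced"
    group_alpha: float = 0.05

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and return (and write) the summary dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.model_copy(update={"synth": config.synth.model_copy(update={"seed": config.seed})})
    log.info("simulate: %d subjects, seed %d", cfg.synth.n_subjects, cfg.seed)
    subjects, manifest = generate_cohort(cfg.synth)
    results: dict = {"config": json.loads(cfg.model_dump_json()), "manifest": _jsonable(manifest)}

    # --- behavior ---
    events_dir = out / "events"
    events_dir.mkdir(exist_ok=True)
    for s in subjects:
        df = s.trace
        io.write_events(df, events_dir / f"sub-{s.subject_id:02d}_events.tsv")
    free_high = []
    for s in subjects:
        mask = (s.trace["choice_type"] == "free") & (s.trace["responded"] == 1)
        hit = s.trace.loc[mask, "chosen_cs"].to_numpy() == s.trace.loc[mask, "high_cs"].to_numpy()
        free_high.append(float(hit.mean()))
    curves = group_inference.choice_reversal_curves(
        [s.choices for s in subjects], [s.schedules for s in subjects]
    )
    curves.to_csv(out / "choice_curves.tsv", sep="\t", index=False)
    t_high = group_inference.one_sample_t(np.asarray(free_high), 0.5)
    results["behavior"] = {
        "free_choice_high_rate": float(np.mean(free_high)),
        "high_vs_chance_t": t_high.statistic,
        "high_vs_chance_p": t_high.p,
    }

    # --- model fitting ---
    log.info("fit: MAP per subject")
    fits = []
    zs = []
    for s in subjects:
        params, nll = model_fitting.fit_subject(
            s.schedules, s.choices, c_max=cfg.c_max, n_restarts=cfg.fit_restarts,
            seed=cfg.seed + s.subject_id,
        )
        trace, _ = rl_model.run_model(s.schedules, s.choices, params)
        zs.append(rl_model.choice_probability_correlation(trace))
        fits.append({"subject": s.subject_id, "alpha": params.alpha, "c": params.c, "nll": nll,
                     "alpha_true": s.params.alpha, "c_true": s.params.c})
    fit_df = pd.DataFrame(fits)
    fit_df.to_csv(out / "fits.tsv", sep="\t", index=False)
    z_arr = np.asarray([z for z in zs if np.isfinite(z)])
    t_fit = group_inference.one_sample_t(z_arr) if z_arr.size >= 3 else None
    results["model_fit"] = {
        "alpha_recovery_r": float(np.corrcoef(fit_df["alpha_true"], fit_df["alpha"])[0, 1]),
        "mean_choice_prob_z": float(np.mean(z_arr)),
        "choice_prob_z_t": t_fit.statistic if t_fit else float("nan"),
        "choice_prob_z_p": t_fit.p if t_fit else float("nan"),
    }

    has_bold = bool(subjects and subjects[0].bold)
    if has_bold:
        # --- univariate PE GLM at midbrain ---
        log.info("glm: PE-modulated FIR betas at midbrain")
        pe = [coupling.pe_modulated_betas(s) for s in subjects]
        ipe = np.array([d["abs_iPE"] for d in pe])
        vpp = np.array([d["vPE_pos"] for d in pe])
        t_ipe = group_inference.one_sample_t(ipe)
        t_vpp = group_inference.one_sample_t(vpp)
        r_iv = group_inference.across_subject_correlation(ipe, vpp)
        results["univariate"] = {
            "midbrain_ipe_t": t_ipe.statistic, "midbrain_ipe_p": t_ipe.p,
            "midbrain_vpe_pos_t": t_vpp.statistic, "midbrain_vpe_pos_p": t_vpp.p,
            "ipe_vpe_correlation_r": r_iv.statistic, "ipe_vpe_correlation_p": r_iv.p,
        }
        dir_betas = [coupling.directional_ipe_betas(s) for s in subjects]
        sw = np.array([d["sw_sv"] for d in dir_betas])
        sv = np.array([d["sv_sw"] for d in dir_betas])
        keep = np.isfinite(sw) & np.isfinite(sv)
        if keep.sum() >= 3:
            r_dir = group_inference.across_subject_correlation(sw[keep], sv[keep])
            results["univariate"]["directional_ipe_r"] = r_dir.statistic
            results["univariate"]["directional_ipe_p"] = r_dir.p

        # --- MVPA at the OFC and amygdala ROIs (+ optional searchlight) ---
        log.info("mvpa: template-correlation at ROI spheres")
        label_means = {roi: {lab: [] for lab in pattern_analysis.LABELS}
                       for roi in ("ofc", "amygdala", "control")}
        sim_tables = []
        for s in subjects:
            for roi in label_means:
                vox = np.argwhere(s.masks[roi])
                table = pattern_analysis.roi_similarity_table(
                    s, vox, test_trials=cfg.mvpa_test_trials
                )
                for lab in pattern_analysis.LABELS:
                    label_means[roi][lab].append(float(table[f"z_{lab}"].mean()))
                if roi == "ofc":
                    sim_tables.append(table)
        mvpa = {}
        for roi, d in label_means.items():
            sisv = np.asarray(d["SISV"])
            for other in ("DISV", "SIDV", "DIDV"):
                t = group_inference.paired_t(sisv, np.asarray(d[other]))
                mvpa[f"{roi}_SISV_minus_{other}_t"] = t.statistic
                mvpa[f"{roi}_SISV_minus_{other}_p"] = t.p
        results["mvpa"] = mvpa
        if cfg.searchlight:
            log.info("mvpa: searchlight maps")
            contrasts = []
            for s in subjects:
                maps = pattern_analysis.searchlight_run(s, radius=cfg.searchlight_radius)
                contrasts.append(pattern_analysis.label_contrast(maps, "SISV", "DISV"))
            t_map, p_map = group_inference.group_map_ttest(contrasts)
            surv, _ = group_inference.small_volume_correct(
                p_map, subjects[0].masks["ofc"], alpha=cfg.group_alpha
            )
            io.write_volume(t_map, out / "searchlight_sisv_disv_t.nii.gz")
            flat = np.nanargmax(np.where(np.isnan(t_map), -np.inf, t_map))
            peak = np.unravel_index(flat, t_map.shape)
            results["searchlight"] = {
                "peak_voxel": [int(v) for v in peak],
                "peak_in_ofc": bool(subjects[0].masks["ofc"][peak]),
                "n_svc_survivors_ofc": int(surv.sum()),
            }

        # --- coupling ---
        log.info("coupling: OFC update x midbrain response")
        coup_betas, summaries = [], []
        for s, table in zip(subjects, sim_tables):
            info = coupling.identity_information_trace(table)
            coup_betas.append(coupling.update_modulated_glm(s, info))
            summaries.append(coupling.reversal_update_summary(info, s))
        coup_betas = np.asarray(coup_betas)
        t_coup = group_inference.one_sample_t(coup_betas)
        r_fig6a = group_inference.across_subject_correlation(ipe, np.asarray(summaries))
        results["coupling"] = {
            "update_glm_mean_beta": float(coup_betas.mean()),
            "update_glm_t": t_coup.statistic, "update_glm_p": t_coup.p,
            "ipe_vs_ofc_update_r": r_fig6a.statistic, "ipe_vs_ofc_update_p": r_fig6a.p,
        }

        # --- sniff features ---
        peaks_high, peaks_low, dur_high, dur_low = [], [], [], []
        for s in subjects:
            ph, pl, dh, dl = [], [], [], []
            for run in range(len(s.sniff_traces)):
                timing = s.onsets[run]
                trace = s.run_trace(run)
                responded = timing["responded"].to_numpy() == 1
                feats, _ = io.sniff_features(
                    s.sniff_traces[run], timing.loc[responded, "onset_us"].to_numpy(),
                    fs=cfg.synth.sniff_hz,
                )
                v = trace.loc[responded, "V"].to_numpy()
                ph.append(feats.loc[v == 1, "peak"].mean())
                pl.append(feats.loc[v == 0, "peak"].mean())
                dh.append(feats.loc[v == 1, "duration"].mean())
                dl.append(feats.loc[v == 0, "duration"].mean())
            peaks_high.append(np.nanmean(ph)); peaks_low.append(np.nanmean(pl))
            dur_high.append(np.nanmean(dh)); dur_low.append(np.nanmean(dl))
        t_peak = group_inference.paired_t(np.asarray(peaks_high), np.asarray(peaks_low))
        results["sniff"] = {
            "peak_high_minus_low": float(np.mean(peaks_high) - np.mean(peaks_low)),
            "peak_intensity_t": t_peak.statistic, "peak_intensity_p": t_peak.p,
            "duration_high_minus_low": float(np.mean(dur_high) - np.mean(dur_low)),
        }

    with open(out / "results.json", "w") as fh:
        json.dump(_jsonable(results), fh, indent=2)
    log.info("pipeline complete: %s", out / "results.json")
    return results
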