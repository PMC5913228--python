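"""Synthetic cohorts: behavior plus voxel-level neural data with planted effects.

The generator emulates the study conditions — 23 subjects, 3 runs of 84
trials, subject-specific (alpha, c) drawn from beta parent
distributions — and plants three neural effects with known ground truth:

* a "midbrain" ROI whose odor-evoked response amplitude scales with the
  unsigned identity PE and the positive value PE;
* an "OFC" ROI whose CS-evoked multivoxel pattern expresses the current
  task state, with the outcome-identity component dominant (an
  "amygdala" ROI mirrors this with the CS-value component dominant);
* a trial-level coupling: after each odor delivery the expressed OFC
  pattern moves toward the revealed state's pattern by a step that grows
  with the midbrain response on that trial (strength kappa), so larger
  error responses produce larger next-trial expectation updates.

Neural time series are built from the same regressor constructions the
analysis GLMs use (FIR kernel for odor responses, HRF-convolved boxcars
for CS events), so noiseless rounds trip exactly.  Everything is
deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import glm_fir, rl_model, task_design


class SyntheticConfig(BaseModel):
    """Fully determines a cohort given its seed.  Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # cohort structure
    n_subjects: int = 23
    n_runs: int = 3
    n_trials_per_run: int = 84
    block_lengths: tuple[int, ...] = (9, 12)
    forced_fraction: float = 2.0 / 3.0
    miss_rate: float = 0.0
    # timing (seconds)
    tr: float = 2.0
    trial_spacing_mean: float = 15.0
    trial_spacing_jitter: float = 2.0
    cue_duration: float = 4.0
    choice_to_us: float = 2.0
    # geometry
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    # RL parameter parent distributions (c on its natural scale)
    alpha_mean: float = 0.5
    alpha_sd: float = 0.15
    c_mean: float = 1.5
    c_sd: float = 0.5
    c_max: float = 5.0
    # planted neural effects
    beta_ipe: float = 1.0  # response units per unit |iPE|
    beta_vpe_pos: float = 1.0  # response units per unit vPE+
    us_baseline: float = 0.5  # unmodulated odor response amplitude
    subject_gain_sd: float = 0.25  # across-subject spread of the midbrain gain
    amp_noise_sd: float = 0.5  # trial-level midbrain amplitude fluctuation (response units)
    pattern_strength: float = 1.0  # identity-component amplitude (OFC codes identity only)
    value_pattern_strength: float = 1.0  # CS-value component amplitude (amygdala codes value only)
    unique_pattern_strength: float = 0.3  # state-unique component
    baseline_update: float = 0.2  # pattern step toward the revealed state, at zero midbrain amp
    coupling_strength: float = 0.25  # kappa: extra step per unit midbrain amplitude
    noise_sd: float = 1.0
    # HRF
    hrf_peak: float = 5.0
    hrf_undershoot: float = 15.0
    # respiration trace
    sniff_hz: float = 10.0
    sniff_bump_high: float = 0.5  # extra sniff amplitude for high-intensity odors
    seed: int = 0


def _beta_draw(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Beta(mean, sd) draws on (0,1); sd = 0 degenerates to the mean."""
    if sd <= 0:
        return np.full(n, mean)
    if sd**2 >= mean * (1 - mean):
        raise ValueError(f"beta sd {sd} too large for mean {mean}")
    nu = mean * (1 - mean) / sd**2 - 1.0
    return rng.beta(mean * nu, (1 - mean) * nu, size=n)


def _box(grid: tuple[int, int, int], fr: tuple[float, ...]) -> np.ndarray:
    """Boolean box mask from fractional (x0,x1,y0,y1,z0,z1) coordinates."""
    m = np.zeros(grid, dtype=bool)
    sl = []
    for ax in range(3):
        a = int(round(fr[2 * ax] * grid[ax]))
        b = max(a + 1, int(round(fr[2 * ax + 1] * grid[ax])))
        sl.append(slice(a, b))
    m[sl[0], sl[1], sl[2]] = True
    return m


def default_rois(grid_dims: tuple[int, int, int] = (16, 16, 16)) -> dict[str, np.ndarray]:
    """Named ROI masks on the synthetic grid: disjoint boxes inside an in-brain cube."""
    rois = {
        "brain": _box(grid_dims, (0.07, 0.94, 0.07, 0.94, 0.07, 0.94)),
        "midbrain": _box(grid_dims, (0.38, 0.57, 0.38, 0.57, 0.13, 0.32)),
        "ofc": _box(grid_dims, (0.19, 0.50, 0.63, 0.88, 0.32, 0.57)),
        "amygdala": _box(grid_dims, (0.63, 0.88, 0.63, 0.82, 0.19, 0.38)),
        "control": _box(grid_dims, (0.63, 0.88, 0.19, 0.44, 0.63, 0.88)),
    }
    names = [n for n in rois if n != "brain"]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.any(rois[a] & rois[b]):
                raise ValueError(f"ROI overlap between {a!r} and {b!r}")
        if np.any(rois[a] & ~rois["brain"]):
            raise ValueError(f"ROI {a!r} extends outside the in-brain mask")
    return rois


@dataclass
class SubjectDataset:
    """One subject's complete synthetic dataset (behavior always; BOLD optional)."""

    subject_id: int
    schedules: list[task_design.SessionSchedule]
    choices: np.ndarray
    params: rl_model.ModelParams
    trace: pd.DataFrame
    masks: dict[str, np.ndarray]
    tr: float
    bold: list[np.ndarray] = field(default_factory=list)  # per run, (x, y, z, t)
    onsets: list[pd.DataFrame] = field(default_factory=list)  # per run
    nuisance: list[dict[str, np.ndarray]] = field(default_factory=list)  # per run, at TR
    sniff_traces: list[np.ndarray] = field(default_factory=list)  # per run, at sniff_hz
    gain: float = 1.0
    state_patterns: dict[str, np.ndarray] = field(default_factory=dict)  # roi -> (4, n_vox)

    def run_trace(self, run: int) -> pd.DataFrame:
        return self.trace[self.trace["run"] == run].reset_index(drop=True)


def generate_behavior_cohort(config: SyntheticConfig) -> list[SubjectDataset]:
    """Schedules, RL parameters, choices and latent traces for every subject."""
    rng = np.random.default_rng(config.seed)
    alphas = np.clip(_beta_draw(rng, config.alpha_mean, config.alpha_sd, config.n_subjects), 0.02, 0.98)
    cs = _beta_draw(rng, config.c_mean / config.c_max, config.c_sd / config.c_max, config.n_subjects)
    cs = np.clip(cs * config.c_max, 0.0, config.c_max)
    masks = default_rois(config.grid_dims)
    subjects = []
    for j in range(config.n_subjects):
        params = rl_model.ModelParams(alpha=float(alphas[j]), c=float(cs[j]))
        schedules = []
        for r in range(config.n_runs):
            # first reversal kind counterbalanced across subjects and runs
            kind = task_design.VREV if (j + r) % 2 == 0 else task_design.IREV
            schedules.append(
                task_design.generate_schedule(
                    n_trials=config.n_trials_per_run,
                    block_lengths=config.block_lengths,
                    first_reversal_kind=kind,
                    seed=int(rng.integers(2**31 - 1)),
                    forced_fraction=config.forced_fraction,
                )
            )
        choices, trace = rl_model.simulate_agent(
            schedules, params, seed=int(rng.integers(2**31 - 1)), miss_rate=config.miss_rate
        )
        subjects.append(
            SubjectDataset(
                subject_id=j,
                schedules=schedules,
                choices=choices,
                params=params,
                trace=trace,
                masks=masks,
                tr=config.tr,
            )
        )
    return subjects


def _run_timing(n_trials: int, config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    spacing = config.trial_spacing_mean + rng.uniform(
        -config.trial_spacing_jitter, config.trial_spacing_jitter, size=n_trials
    )
    starts = 10.0 + np.concatenate([[0.0], np.cumsum(spacing[:-1])])
    rt = rng.uniform(0.4, 1.2, size=n_trials)
    cue = starts
    choice = cue + config.cue_duration + rt
    us = choice + config.choice_to_us
    rating = us + 3.5
    return pd.DataFrame(
        {"trial": np.arange(n_trials), "onset_cue": cue, "onset_choice": choice,
         "onset_us": us, "onset_rating": rating}
    )


def _state_patterns(
    n_vox: int, rng: np.random.Generator, identity_strength: float, value_strength: float,
    unique_strength: float,
) -> np.ndarray:
    """(4, n_vox) patterns: shared identity + CS-value + unique components."""
    ident_comp = rng.standard_normal((2, n_vox))
    value_comp = rng.standard_normal((2, n_vox))
    unique = rng.standard_normal((4, n_vox))
    w = np.empty((4, n_vox))
    for s, state in enumerate(task_design.enumerate_states()):
        i = 0 if state.identity == task_design.SWEET else 1
        v = state.high_cs
        w[s] = (
            identity_strength * ident_comp[i]
            + value_strength * value_comp[v]
            + unique_strength * unique[s]
        )
    return w


def _sniff_trace(
    n_scans: int, onset_us: np.ndarray, values: np.ndarray, config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Respiration-like trace at sniff_hz: slow sinusoid + noise + intensity-scaled US bumps."""
    fs = config.sniff_hz
    t = np.arange(int(n_scans * config.tr * fs)) / fs
    trace = 0.5 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    trace += 0.2 * rng.standard_normal(t.shape)
    for onset, v in zip(onset_us, values):
        # high-intensity odors evoke deeper and longer sniffs: larger bump,
        # later peak, wider envelope
        amp = 1.0 + (config.sniff_bump_high if v == 1 else 0.0)
        center = onset + (1.4 if v == 1 else 1.0)
        width = 1.0 if v == 1 else 0.7
        trace += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return trace


def generate_neural_run(
    subject: SubjectDataset, run: int, config: SyntheticConfig, rng: np.random.Generator
) -> None:
    """Attach one run of BOLD, onsets and nuisance traces to ``subject`` in place."""
    trace = subject.run_trace(run)
    n_trials = len(trace)
    timing = _run_timing(n_trials, config, rng)
    n_scans = int(np.ceil((timing["onset_us"].iloc[-1] + 24.0) / config.tr))
    grid = config.grid_dims
    masks = subject.masks
    bold = np.zeros(grid + (n_scans,))

    responded = trace["responded"].to_numpy() == 1
    # --- midbrain: odor-evoked amplitude from the planted PE betas ---
    abs_ipe = np.where(responded, trace["abs_iPE"].to_numpy(), 0.0)
    vpe_pos = np.where(responded, trace["vPE_pos"].to_numpy(), 0.0)
    # trial-level amplitude fluctuation: the component the coupling analyses
    # trace into next-trial OFC updates over and above the deterministic PE part
    amp = subject.gain * (
        config.us_baseline
        + config.beta_ipe * abs_ipe
        + config.beta_vpe_pos * vpe_pos
        + config.amp_noise_sd * rng.standard_normal(n_trials)
    )
    amp = np.where(responded, amp, 0.0)
    kernel = glm_fir.fir_hrf_kernel(
        config.tr, peak=config.hrf_peak, undershoot=config.hrf_undershoot
    )
    us_scans = np.rint(timing["onset_us"].to_numpy() / config.tr).astype(int)
    mid_series = np.zeros(n_scans)
    for s, a in zip(us_scans, amp):
        hi = min(s + kernel.shape[0], n_scans)
        mid_series[s:hi] += a * kernel[: hi - s]
    bold[masks["midbrain"]] += mid_series

    # --- OFC / amygdala: CS-evoked state patterns with coupled updating ---
    roi_patterns = subject.state_patterns  # fixed across runs; set by generate_cohort
    state_ids = trace["state_id"].to_numpy()
    events = [
        {
            "onset": timing["onset_cue"].iloc[t],
            "duration": timing["onset_choice"].iloc[t] - timing["onset_cue"].iloc[t],
            "name": f"trial_{t:03d}",
        }
        for t in range(n_trials)
    ]
    trial_design = glm_fir.build_event_design(
        events, n_scans, tr=config.tr, hrf_peak=config.hrf_peak,
        hrf_undershoot=config.hrf_undershoot, add_constant=False,
    )
    X = trial_design.matrix  # (n_scans, n_trials), column t = trial t's regressor
    for roi, w in roi_patterns.items():
        expressed = np.empty((n_trials, w.shape[1]))
        e = w[state_ids[0]].copy()  # familiarized on day 1: start at the true state pattern
        for t in range(n_trials):
            expressed[t] = e
            if responded[t]:
                step = np.clip(
                    config.baseline_update + config.coupling_strength * amp[t], 0.0, 1.0
                )
                e = e + step * (w[state_ids[t]] - e)
        bold[masks[roi]] += (X @ expressed).T

    # --- noise everywhere in brain ---
    if config.noise_sd > 0:
        bold[masks["brain"]] += config.noise_sd * rng.standard_normal(
            (int(masks["brain"].sum()), n_scans)
        )

    values = np.where(responded, trace["V"].to_numpy(), 0)
    sniff = _sniff_trace(n_scans, timing["onset_us"].to_numpy()[responded], values[responded],
                         config, rng)
    # nuisance copies at scanner resolution (TR = 2 s -> 0.5 Hz)
    step = int(config.sniff_hz * config.tr)
    sniff_tr = sniff[: n_scans * step : step].copy()
    rating_tr = np.convolve(rng.standard_normal(n_scans), np.ones(5) / 5, mode="same")

    timing["responded"] = responded.astype(int)
    subject.bold.append(bold)
    subject.onsets.append(timing)
    subject.nuisance.append({"sniff": sniff_tr, "rating": rating_tr})
    subject.sniff_traces.append(sniff)


def generate_cohort(
    config: SyntheticConfig, include_neural: bool = True
) -> tuple[list[SubjectDataset], dict]:
    """Full cohort plus a ground-truth manifest of every planted effect size."""
    subjects = generate_behavior_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    for subject in subjects:
        subject.gain = float(
            np.clip(1.0 + config.subject_gain_sd * rng.standard_normal(), 0.2, None)
        )
        subject.state_patterns = {
            # OFC encodes expected outcome identity, amygdala the CS-value
            # assignment; each with a small state-unique component.
            "ofc": _state_patterns(
                int(subject.masks["ofc"].sum()), rng, config.pattern_strength,
                0.0, config.unique_pattern_strength,
            ),
            "amygdala": _state_patterns(
                int(subject.masks["amygdala"].sum()), rng, 0.0,
                config.value_pattern_strength, config.unique_pattern_strength,
            ),
        }
        if include_neural:
            for r in range(config.n_runs):
                generate_neural_run(subject, r, config, rng)
    manifest = {
        "n_subjects": config.n_subjects,
        "n_runs": config.n_runs,
        "n_trials_per_run": config.n_trials_per_run,
        "beta_ipe": config.beta_ipe,
        "beta_vpe_pos": config.beta_vpe_pos,
        "pattern_strength": config.pattern_strength,
        "value_pattern_strength": config.value_pattern_strength,
        "coupling_strength": config.coupling_strength,
        "baseline_update": config.baseline_update,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "subject_gains": [s.gain for s in subjects],
        "subject_alpha": [s.params.alpha for s in subjects],
        "subject_c": [s.params.c for s in subjects],
    }
    return subjects, manifest
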