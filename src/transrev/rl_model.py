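"""Reinforcement-learning model of the transreinforcer reversal task.

The agent maintains a cached expected value per CS (EV_1, EV_2, both
initialised at 0) and a single shared expected identity EI = P(sweet)
(initialised at 0.5).  On every responded trial three prediction errors
are computed from the delivered odor's value V in {0, 1} and identity
I in {0, 1}:

* value PE for the chosen CS,       vPE = V - EV_S
* fictive PE for the unchosen CS,   fPE = (-V + 1) - EV_NS
* identity PE (shared),             iPE = I - EI

each driving a delta-rule update with learning rate alpha.  The fictive
update exploits the task structure: within a block the two CSs always
deliver anti-correlated values, so the forgone outcome is known.  Choice
follows a softmax on the two EVs with slope theta = 3**c - 1, a
parameterisation that accommodates near-deterministic choice strategies
at moderate c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _core
from .task_design import SessionSchedule

P_CLIP = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """RL parameters.

    alpha : shared learning rate in (0, 1).
    c : softmax slope parameter, c >= 0; theta = 3**c - 1.
    alpha_fictive : learning rate for the fictive update; defaults to alpha.
    use_fictive : whether the unchosen CS is updated at all.
    """

    alpha: float
    c: float
    alpha_fictive: float | None = None
    use_fictive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.c < 0.0 or not np.isfinite(self.c):
            raise ValueError(f"c must be finite and >= 0, got {self.c}")

    @property
    def theta(self) -> float:
        return 3.0**self.c - 1.0

    @property
    def alpha_f(self) -> float:
        return self.alpha if self.alpha_fictive is None else self.alpha_fictive


def softmax_prob(ev_1: float, ev_2: float, theta: float) -> float:
    """P(choose CS 1) = exp(theta*EV_1) / (exp(theta*EV_1) + exp(theta*EV_2)).

    Implemented in log-sum-exp form so large slopes do not overflow.
    """
    if not (np.isfinite(ev_1) and np.isfinite(ev_2) and np.isfinite(theta)):
        raise ValueError("softmax_prob requires finite inputs")
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    m = max(theta * ev_1, theta * ev_2)
    return float(np.exp(theta * ev_1 - m) / (np.exp(theta * ev_1 - m) + np.exp(theta * ev_2 - m)))


def step_update(
    ev: tuple[float, float],
    ei: float,
    chosen_cs: int,
    outcome: tuple[int, int],
    params: ModelParams,
) -> dict:
    """One trial's worth of prediction errors and delta-rule updates.

    ``outcome`` is the delivered (V, I).  Returns the post-update
    expectations together with the three PEs.
    """
    v, i = outcome
    if v not in (0, 1) or i not in (0, 1):
        raise ValueError(f"outcome (V, I) must be binary, got {(v, i)}")
    ev = list(ev)
    vpe = v - ev[chosen_cs]
    ev[chosen_cs] += params.alpha * vpe
    fpe = np.nan
    if params.use_fictive:
        fpe = (1.0 - v) - ev[1 - chosen_cs]
        ev[1 - chosen_cs] += params.alpha_f * fpe
    ipe = i - ei
    ei += params.alpha * ipe
    return {"ev": (ev[0], ev[1]), "ei": ei, "vpe": vpe, "fpe": fpe, "ipe": ipe}


def _stack_schedules(schedules: list[SessionSchedule]) -> pd.DataFrame:
    """Concatenate runs into one trial table with a run column and run-start flags."""
    frames = []
    for r, sched in enumerate(schedules):
        df = sched.to_frame()
        df.insert(0, "run", r)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["run_start"] = (out["trial"] == 0).astype(np.int8)
    return out


def run_model(
    schedules: SessionSchedule | list[SessionSchedule],
    choices: np.ndarray,
    params: ModelParams,
    reset_between_runs: bool = False,
    likelihood_trials: str = "free",
) -> tuple[pd.DataFrame, float]:
    """Latent traces and choice negative log-likelihood for observed choices.

    Parameters
    ----------
    schedules : one schedule or the list of a subject's runs.  Expectations
        carry over across runs by default (the CS-US structure persists);
        set ``reset_between_runs`` to re-initialise each run.
    choices : per-trial chosen CS (0/1), -1 for missed trials.
    likelihood_trials : ``"free"`` (default) scores free-choice trials only
        — forced choices are fully cued and carry no information about the
        parameters — or ``"all"`` to score every responded trial.

    Returns
    -------
    (trace, nll) : trace is one row per trial with pre-choice EV_1/EV_2/EI,
    choice probabilities, delivered V/I and the three PEs (NaN on missed
    trials); nll is -sum(log P(chosen)) over the likelihood trial set.
    """
    if isinstance(schedules, SessionSchedule):
        schedules = [schedules]
    if not schedules or not any(s.n_trials for s in schedules):
        raise ValueError("empty schedule")
    if likelihood_trials not in ("free", "all"):
        raise ValueError(f"likelihood_trials must be 'free' or 'all', got {likelihood_trials!r}")
    table = _stack_schedules(schedules)
    choices = np.asarray(choices, dtype=np.int8)
    if choices.shape[0] != len(table):
        raise ValueError(f"choices length {choices.shape[0]} != total trials {len(table)}")

    # deterministic outcomes given the state and the chosen CS
    value = np.where(choices == table["high_cs"].to_numpy(), 1, 0).astype(np.int8)
    ident = (table["identity"].to_numpy() == "sweet").astype(np.int8)
    free = (table["choice_type"].to_numpy() == "free").astype(np.int8)
    run_start = table["run_start"].to_numpy().astype(np.int8)

    ev1, ev2, ei, p1, ipe, vpe, fpe = _core.trace_kernel(
        choices,
        value,
        ident,
        run_start,
        reset_between_runs,
        params.alpha,
        params.alpha_f,
        params.alpha,
        params.theta,
        params.use_fictive,
    )
    trace = table.copy()
    trace["chosen_cs"] = choices
    trace["responded"] = (choices >= 0).astype(int)
    trace["V"] = np.where(choices >= 0, value, -1)
    trace["I"] = ident
    trace["EV_1"] = ev1
    trace["EV_2"] = ev2
    trace["EI"] = ei
    trace["P_1"] = p1
    trace["P_2"] = 1.0 - p1
    trace["iPE"] = ipe
    trace["vPE"] = vpe
    trace["fPE"] = fpe
    trace["abs_iPE"] = np.abs(ipe)
    trace["vPE_pos"] = np.where(np.isnan(vpe), np.nan, np.maximum(vpe, 0.0))
    trace["vPE_neg"] = np.where(np.isnan(vpe), np.nan, np.minimum(vpe, 0.0))

    nll = _core.nll_kernel(
        choices,
        value,
        free,
        run_start,
        reset_between_runs,
        params.alpha,
        params.alpha_f,
        params.theta,
        params.use_fictive,
        likelihood_trials == "all",
    )
    return trace, float(nll)


def simulate_agent(
    schedules: SessionSchedule | list[SessionSchedule],
    params: ModelParams,
    seed: int = 0,
    reset_between_runs: bool = False,
    miss_rate: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate choices from the generative model.

    Forced trials follow the cued CS; free trials sample
    Bernoulli(P_1).  Missed responses (optional) are drawn independently
    at ``miss_rate`` and experience no outcome.  Deterministic under
    ``seed``.  Returns (choices, trace) with the trace recomputed by
    :func:`run_model` so simulation and scoring share one code path.
    """
    if isinstance(schedules, SessionSchedule):
        schedules = [schedules]
    table = _stack_schedules(schedules)
    rng = np.random.default_rng(seed)
    n = len(table)
    high_cs = table["high_cs"].to_numpy()
    forced_cs = table["forced_cs"].to_numpy()
    is_free = table["choice_type"].to_numpy() == "free"
    run_start = table["run_start"].to_numpy()

    choices = np.full(n, -1, dtype=np.int8)
    ev = np.zeros(2)
    theta = params.theta
    for t in range(n):
        if reset_between_runs and run_start[t]:
            ev[:] = 0.0
        if miss_rate > 0 and rng.random() < miss_rate:
            continue
        if is_free[t]:
            p1 = softmax_prob(ev[0], ev[1], theta)
            c = 0 if rng.random() < p1 else 1
        else:
            c = int(forced_cs[t])
        choices[t] = c
        v = 1.0 if c == high_cs[t] else 0.0
        ev[c] += params.alpha * (v - ev[c])
        if params.use_fictive:
            ev[1 - c] += params.alpha_f * ((1.0 - v) - ev[1 - c])
    trace, _ = run_model(schedules, choices, params, reset_between_runs=reset_between_runs)
    return choices, trace


def choice_probability_correlation(trace: pd.DataFrame) -> float:
    """Fisher-z correlation between model choice probability and actual choice.

    Computed over responded free-choice trials: r between P_1 and the
    indicator of choosing CS 1, z-transformed.  A behavioral model-fit
    summary statistic.
    """
    mask = (trace["choice_type"] == "free") & (trace["responded"] == 1)
    p = trace.loc[mask, "P_1"].to_numpy()
    y = (trace.loc[mask, "chosen_cs"].to_numpy() == 0).astype(float)
    if p.size < 3 or np.std(p) == 0 or np.std(y) == 0:
        return np.nan
    r = float(np.corrcoef(p, y)[0, 1])
    r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    return float(np.arctanh(r))
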