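"""Numba-compiled inner loops for the reinforcement-learning model.

These kernels are deliberately minimal: flat arrays in, flat arrays out.
The public API (:mod:`transrev.rl_model`) wraps them in labelled tables.
Choice likelihood depends only on the two expected values, so the
negative-log-likelihood kernel skips the identity expectation entirely.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PCLIP = 1e-12


@njit(cache=True)
def nll_kernel(
    chosen: np.ndarray,  # int8, -1 = missed
    value: np.ndarray,  # int8, delivered V in {0,1}; undefined where missed
    free: np.ndarray,  # int8, 1 on free-choice trials
    run_start: np.ndarray,  # int8, 1 where expectations reset (if resetting)
    reset_runs: bool,
    alpha_v: float,
    alpha_f: float,
    theta: float,
    use_fpe: bool,
    include_forced: bool,
) -> float:
    """Negative log-likelihood of a choice sequence under the softmax RL model."""
    ev = np.zeros(2)
    nll = 0.0
    for t in range(chosen.shape[0]):
        if reset_runs and run_start[t] == 1:
            ev[0] = 0.0
            ev[1] = 0.0
        c = chosen[t]
        if c < 0:
            continue  # missed: no likelihood, no update
        if free[t] == 1 or include_forced:
            # numerically stable softmax
            m = theta * ev[0] if ev[0] > ev[1] else theta * ev[1]
            z = np.exp(theta * ev[0] - m) + np.exp(theta * ev[1] - m)
            p = np.exp(theta * ev[c] - m) / z
            if p < _PCLIP:
                p = _PCLIP
            nll -= np.log(p)
        v = float(value[t])
        ev[c] += alpha_v * (v - ev[c])
        if use_fpe:
            ev[1 - c] += alpha_f * ((1.0 - v) - ev[1 - c])
    return nll


@njit(cache=True)
def nll_many(
    chosen: np.ndarray,  # int8 (n_subjects, n_trials), -1 = missed/padding
    value: np.ndarray,  # int8, same shape
    free: np.ndarray,  # int8, same shape
    run_start: np.ndarray,  # int8, same shape
    reset_runs: bool,
    alpha_v: np.ndarray,  # float64 (n_subjects,)
    alpha_f: np.ndarray,
    theta: np.ndarray,
    use_fpe: bool,
    include_forced: bool,
) -> np.ndarray:
    """Per-subject NLL for a cohort, one parameter vector per subject."""
    n_sub = chosen.shape[0]
    out = np.empty(n_sub)
    for j in range(n_sub):
        out[j] = nll_kernel(
            chosen[j],
            value[j],
            free[j],
            run_start[j],
            reset_runs,
            alpha_v[j],
            alpha_f[j],
            theta[j],
            use_fpe,
            include_forced,
        )
    return out


@njit(cache=True)
def trace_kernel(
    chosen: np.ndarray,
    value: np.ndarray,
    ident: np.ndarray,  # int8, delivered I in {0,1}
    run_start: np.ndarray,
    reset_runs: bool,
    alpha_v: float,
    alpha_f: float,
    alpha_i: float,
    theta: float,
    use_fpe: bool,
):
    """Full latent traces: pre-update EV/EI, choice probabilities, and PEs.

    Returns arrays aligned to trials; prediction errors are NaN on missed
    trials (no outcome is experienced, so no update occurs either).
    """
    n = chosen.shape[0]
    ev1 = np.empty(n)
    ev2 = np.empty(n)
    ei = np.empty(n)
    p1 = np.empty(n)
    ipe = np.full(n, np.nan)
    vpe = np.full(n, np.nan)
    fpe = np.full(n, np.nan)
    ev = np.zeros(2)
    e_i = 0.5
    for t in range(n):
        if reset_runs and run_start[t] == 1:
            ev[0] = 0.0
            ev[1] = 0.0
            e_i = 0.5
        ev1[t] = ev[0]
        ev2[t] = ev[1]
        ei[t] = e_i
        m = theta * ev[0] if ev[0] > ev[1] else theta * ev[1]
        z = np.exp(theta * ev[0] - m) + np.exp(theta * ev[1] - m)
        p1[t] = np.exp(theta * ev[0] - m) / z
        c = chosen[t]
        if c < 0:
            continue
        v = float(value[t])
        i = float(ident[t])
        vpe[t] = v - ev[c]
        ev[c] += alpha_v * vpe[t]
        if use_fpe:
            fpe[t] = (1.0 - v) - ev[1 - c]
            ev[1 - c] += alpha_f * fpe[t]
        ipe[t] = i - e_i
        e_i += alpha_i * ipe[t]
    return ev1, ev2, ei, p1, ipe, vpe, fpe
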