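"""Parameter estimation for the RL model.

Two estimators are provided.  ``fit_subject`` is a fast per-subject
maximum-likelihood point estimate (bounded multi-start optimisation),
used for parameter- and model-recovery work.  ``fit_hierarchical`` is
the reference method: subject-level parameters are drawn from
independent beta parent distributions whose means come from a truncated
normal hyperprior and standard deviations from a uniform hyperprior,
sampled by Metropolis-within-Gibbs MCMC.  ``compare_models`` ranks the
three model variants (shared learning rate; independent value/fictive
learning rates; no fictive update) by AIC/BIC.

All parameters are sampled on the unit scale: alpha directly, and the
softmax parameter as u = c / c_max with c_max configurable (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from . import _core
from .rl_model import ModelParams, run_model
from .task_design import SessionSchedule

C_MAX_DEFAULT = 5.0
ALPHA_EPS = 1e-3

VARIANTS = {
    # name -> (unit-scale parameter names, uses fictive update)
    "shared_alpha": (("alpha", "c"), True),
    "split_alpha": (("alpha", "alpha_fictive", "c"), True),
    "no_fpe": (("alpha", "c"), False),
}


def _variant_params(x: np.ndarray, variant: str, c_max: float) -> ModelParams:
    names, use_fpe = VARIANTS[variant]
    d = dict(zip(names, x))
    return ModelParams(
        alpha=float(np.clip(d["alpha"], ALPHA_EPS, 1 - ALPHA_EPS)),
        c=float(d["c"]) * c_max,
        alpha_fictive=(
            float(np.clip(d["alpha_fictive"], ALPHA_EPS, 1 - ALPHA_EPS))
            if "alpha_fictive" in d
            else None
        ),
        use_fictive=use_fpe,
    )


def prepare_arrays(
    schedules: SessionSchedule | list[SessionSchedule], choices: np.ndarray
) -> dict[str, np.ndarray]:
    """Flatten a subject's runs into the int8 arrays the NLL kernel consumes."""
    if isinstance(schedules, SessionSchedule):
        schedules = [schedules]
    chosen = np.asarray(choices, dtype=np.int8)
    high_cs, free, run_start = [], [], []
    for sched in schedules:
        df = sched.to_frame()
        high_cs.append(df["high_cs"].to_numpy())
        free.append((df["choice_type"].to_numpy() == "free").astype(np.int8))
        rs = np.zeros(len(df), dtype=np.int8)
        rs[0] = 1
        run_start.append(rs)
    high_cs = np.concatenate(high_cs)
    if chosen.shape[0] != high_cs.shape[0]:
        raise ValueError("choices length does not match schedule length")
    value = np.where(chosen == high_cs, 1, 0).astype(np.int8)
    return {
        "chosen": chosen,
        "value": value,
        "free": np.concatenate(free),
        "run_start": np.concatenate(run_start),
    }


# Weak symmetric Beta(1.5, 1.5) prior on each unit-scale parameter for the
# MAP objective.  With finite reversal-learning data the pure MLE diverges to
# the deterministic corner (alpha -> 1, c -> c_max) whenever the observed
# free choices are fully consistent with the converged values; a weakly
# informative prior removes that boundary pile-up without moving interior
# estimates appreciably.
MAP_PRIOR_A = 1.5


def _map_objective(
    x: np.ndarray, arrs: dict, variant: str, c_max: float, likelihood_trials: str
) -> float:
    nll = _nll(x, arrs, variant, c_max, likelihood_trials)
    xc = np.clip(x, 1e-9, 1 - 1e-9)
    log_prior = (MAP_PRIOR_A - 1) * np.sum(np.log(xc) + np.log1p(-xc))
    return nll - log_prior


def _nll(x: np.ndarray, arrs: dict, variant: str, c_max: float, likelihood_trials: str) -> float:
    p = _variant_params(x, variant, c_max)
    return _core.nll_kernel(
        arrs["chosen"],
        arrs["value"],
        arrs["free"],
        arrs["run_start"],
        False,
        p.alpha,
        p.alpha_f,
        p.theta,
        p.use_fictive,
        likelihood_trials == "all",
    )


def fit_subject(
    schedules: SessionSchedule | list[SessionSchedule],
    choices: np.ndarray,
    variant: str = "shared_alpha",
    c_max: float = C_MAX_DEFAULT,
    n_restarts: int = 5,
    seed: int = 0,
    likelihood_trials: str = "free",
    estimator: str = "map",
) -> tuple[ModelParams, float]:
    """Bounded point estimate for one subject.

    ``estimator="map"`` (default) or ``"mle"`` run L-BFGS-B from
    ``n_restarts`` seeded random initialisations on the unit-scaled
    parameters; ``"bayes"`` returns the posterior mean under the same
    weak prior, computed by grid quadrature (two-parameter variants
    only) — the preferred estimator for parameter-recovery work because
    it averages over the likelihood ridge instead of picking a corner of
    it.  Returns (ModelParams, NLL) with NLL the data likelihood at the
    estimate (prior excluded, so AIC/BIC stay likelihood-based).
    """
    if estimator not in ("map", "mle", "bayes"):
        raise ValueError(f"estimator must be 'map', 'mle' or 'bayes', got {estimator!r}")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; options: {sorted(VARIANTS)}")
    arrs = prepare_arrays(schedules, choices)
    if not np.any((arrs["free"] == 1) & (arrs["chosen"] >= 0)):
        raise ValueError("no responded free-choice trials: likelihood is empty")
    names, _ = VARIANTS[variant]
    ndim = len(names)
    bounds = [(ALPHA_EPS, 1 - ALPHA_EPS)] * ndim
    if estimator == "bayes":
        if ndim != 2:
            raise ValueError("grid posterior-mean estimation supports two-parameter variants only")
        x = _grid_posterior_mean(arrs, variant, c_max, likelihood_trials)
        return _variant_params(x, variant, c_max), float(
            _nll(x, arrs, variant, c_max, likelihood_trials)
        )
    rng = np.random.default_rng(seed)
    objective = _map_objective if estimator == "map" else _nll
    best: tuple[float, np.ndarray] | None = None
    failures = []
    for _ in range(n_restarts):
        x0 = rng.uniform(0.1, 0.9, size=ndim)
        res = minimize(
            objective,
            x0,
            args=(arrs, variant, c_max, likelihood_trials),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if not np.isfinite(res.fun):
            failures.append(res.message)
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x)
    if best is None:
        raise RuntimeError(f"all {n_restarts} optimisation restarts failed: {failures}")
    nll_at_opt = _nll(best[1], arrs, variant, c_max, likelihood_trials)
    return _variant_params(best[1], variant, c_max), float(nll_at_opt)


def _grid_posterior_mean(
    arrs: dict, variant: str, c_max: float, likelihood_trials: str, n_grid: int = 60
) -> np.ndarray:
    """Posterior mean of the two unit-scale parameters on an n x n grid."""
    from scipy.special import logsumexp

    g0 = np.linspace(0.01, 0.99, n_grid)
    g1 = np.linspace(0.005, 0.995, n_grid)
    loglik = np.empty((n_grid, n_grid))
    for i, a in enumerate(g0):
        for j, u in enumerate(g1):
            loglik[i, j] = -_nll(np.array([a, u]), arrs, variant, c_max, likelihood_trials)
    lp = (
        loglik
        + (MAP_PRIOR_A - 1) * (np.log(g0) + np.log1p(-g0))[:, None]
        + (MAP_PRIOR_A - 1) * (np.log(g1) + np.log1p(-g1))[None, :]
    )
    w = np.exp(lp - logsumexp(lp))
    return np.array([float((w.sum(axis=1) * g0).sum()), float((w.sum(axis=0) * g1).sum())])


# ---------------------------------------------------------------------------
# hierarchical Bayesian estimation
# ---------------------------------------------------------------------------


def _beta_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """log Beta(x; mean mu, sd) via the moment parameterisation.

    Valid only when sd**2 < mu*(1-mu); callers enforce that region.
    """
    nu = mu * (1 - mu) / sd**2 - 1.0
    a = mu * nu
    b = (1 - mu) * nu
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) + gammaln(a + b) - gammaln(a) - gammaln(b)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect proposals into (lo, hi); keeps the random walk symmetric."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


@dataclass
class MCMCSettings:
    n_samples: int = 3000
    n_burn: int = 1000
    n_chains: int = 3
    subject_step: float = 0.08
    mu_step: float = 0.05
    sd_step: float = 0.03
    sd_bounds: tuple[float, float] = (0.01, 0.5)
    mu_prior: tuple[float, float] = (0.5, 1.0)  # normal, truncated to (0,1)


@dataclass
class PosteriorSummary:
    """Posterior draws and summaries from the hierarchical fit.

    ``draws`` maps parameter names to (n_chains, n_samples) arrays;
    subject parameters are on the model scale (alpha in (0,1), c in
    (0, c_max)).  ``subject_mean``/``subject_sd`` are per-subject
    posterior moments, ``hyper_mean`` the parent-distribution means.
    """

    draws: dict[str, np.ndarray]
    subject_mean: pd.DataFrame
    subject_sd: pd.DataFrame
    hyper_mean: dict[str, float]
    rhat: dict[str, float]
    acceptance: dict[str, float]
    warnings: list[str] = field(default_factory=list)
    c_max: float = C_MAX_DEFAULT


def _stack_cohort(subjects: list[tuple]) -> dict[str, np.ndarray]:
    """Pad per-subject trial arrays to a common length (padding = missed)."""
    arrs = [prepare_arrays(s, c) for s, c in subjects]
    n = max(a["chosen"].shape[0] for a in arrs)
    out = {}
    for key in ("chosen", "value", "free", "run_start"):
        m = np.full((len(arrs), n), -1 if key == "chosen" else 0, dtype=np.int8)
        for j, a in enumerate(arrs):
            m[j, : a[key].shape[0]] = a[key]
        out[key] = m
    return out


def _cohort_nll(stacked: dict, x: np.ndarray, variant: str, c_max: float) -> np.ndarray:
    """Vector of per-subject NLLs; x is (n_subjects, ndim) unit-scale."""
    names, use_fpe = VARIANTS[variant]
    cols = dict(zip(names, x.T))
    alpha = np.clip(cols["alpha"], ALPHA_EPS, 1 - ALPHA_EPS)
    alpha_f = (
        np.clip(cols["alpha_fictive"], ALPHA_EPS, 1 - ALPHA_EPS)
        if "alpha_fictive" in cols
        else alpha
    )
    theta = 3.0 ** (cols["c"] * c_max) - 1.0
    return _core.nll_many(
        stacked["chosen"],
        stacked["value"],
        stacked["free"],
        stacked["run_start"],
        False,
        np.ascontiguousarray(alpha),
        np.ascontiguousarray(alpha_f),
        np.ascontiguousarray(theta),
        use_fpe,
        False,
    )


def fit_hierarchical(
    subjects: list[tuple],
    variant: str = "shared_alpha",
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    c_max: float = C_MAX_DEFAULT,
) -> PosteriorSummary:
    """Hierarchical Bayesian fit of the cohort by Metropolis-within-Gibbs.

    ``subjects`` is a list of (schedules, choices) pairs.  Each unit-scale
    subject parameter is Beta(mean mu_k, sd sigma_k) with
    mu_k ~ Normal(0.5, 1) truncated to (0,1) and sigma_k ~ Uniform(0.01,
    0.5) (restricted to the valid beta moment region).  Subject
    parameters are updated jointly per subject with reflected Gaussian
    proposals, vectorised across subjects; hyperparameters are updated
    one at a time.  Defaults: 3000 retained samples after 1000 burn-in,
    three chains.  A split-R-hat above 1.1 on any parameter is recorded
    as a warning, never silently dropped.
    """
    if len(subjects) < 2:
        raise ValueError("hierarchical fitting requires >= 2 subjects")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    mcmc = mcmc or MCMCSettings()
    names, _ = VARIANTS[variant]
    ndim = len(names)
    n_sub = len(subjects)
    stacked = _stack_cohort(subjects)
    lo, hi = 1e-4, 1 - 1e-4
    sd_lo, sd_hi = mcmc.sd_bounds
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(mcmc.n_chains)

    keep_x = np.empty((mcmc.n_chains, mcmc.n_samples, n_sub, ndim))
    keep_mu = np.empty((mcmc.n_chains, mcmc.n_samples, ndim))
    keep_sd = np.empty((mcmc.n_chains, mcmc.n_samples, ndim))
    acc_sub = np.zeros(mcmc.n_chains)
    acc_hyp = np.zeros(mcmc.n_chains)
    n_sweeps = mcmc.n_burn + mcmc.n_samples

    for ch in range(mcmc.n_chains):
        rng = np.random.default_rng(chain_seeds[ch])
        x = rng.uniform(0.2, 0.8, size=(n_sub, ndim))
        mu = rng.uniform(0.3, 0.7, size=ndim)
        sd = rng.uniform(0.1, 0.3, size=ndim)
        nll = _cohort_nll(stacked, x, variant, c_max)
        for sweep in range(n_sweeps):
            # --- subject block (vectorised across subjects) ---
            prop = _reflect(x + rng.normal(0, mcmc.subject_step, size=x.shape), lo, hi)
            nll_prop = _cohort_nll(stacked, prop, variant, c_max)
            logr = nll - nll_prop
            for k in range(ndim):
                logr += _beta_logpdf(prop[:, k], mu[k], sd[k])
                logr -= _beta_logpdf(x[:, k], mu[k], sd[k])
            accept = np.log(rng.random(n_sub)) < logr
            x[accept] = prop[accept]
            nll[accept] = nll_prop[accept]
            acc_sub[ch] += accept.mean() / n_sweeps
            # --- hyperparameter block ---
            for k in range(ndim):
                mu_p = float(_reflect(np.array([mu[k] + rng.normal(0, mcmc.mu_step)]), lo, hi)[0])
                sd_p = float(
                    _reflect(np.array([sd[k] + rng.normal(0, mcmc.sd_step)]), sd_lo, sd_hi)[0]
                )
                if sd_p**2 >= mu_p * (1 - mu_p) - 1e-9:
                    continue
                m0, s0 = mcmc.mu_prior
                logr_h = -0.5 * ((mu_p - m0) ** 2 - (mu[k] - m0) ** 2) / s0**2
                logr_h += float(
                    np.sum(_beta_logpdf(x[:, k], mu_p, sd_p) - _beta_logpdf(x[:, k], mu[k], sd[k]))
                )
                if np.log(rng.random()) < logr_h:
                    mu[k], sd[k] = mu_p, sd_p
                    acc_hyp[ch] += 1.0 / (n_sweeps * ndim)
            if sweep >= mcmc.n_burn:
                s = sweep - mcmc.n_burn
                keep_x[ch, s] = x
                keep_mu[ch, s] = mu
                keep_sd[ch, s] = sd

    # assemble draws on the model scale
    draws: dict[str, np.ndarray] = {}
    scale = {name: (c_max if name == "c" else 1.0) for name in names}
    for k, name in enumerate(names):
        draws[f"mu_{name}"] = keep_mu[:, :, k].copy()
        draws[f"sd_{name}"] = keep_sd[:, :, k].copy()
        for j in range(n_sub):
            draws[f"{name}_{j}"] = keep_x[:, :, j, k] * scale[name]

    import arviz  # deferred: slow import, only needed for diagnostics

    rhat = {p: float(arviz.rhat(d)) for p, d in draws.items()}
    warnings = [f"R-hat {v:.3f} > 1.1 for {p}" for p, v in rhat.items() if v > 1.1]

    subject_mean = pd.DataFrame(
        {name: [draws[f"{name}_{j}"].mean() for j in range(n_sub)] for name in names}
    )
    subject_sd = pd.DataFrame(
        {name: [draws[f"{name}_{j}"].std() for j in range(n_sub)] for name in names}
    )
    hyper_mean = {f"mu_{n}": float(draws[f"mu_{n}"].mean()) for n in names}
    hyper_mean.update({f"sd_{n}": float(draws[f"sd_{n}"].mean()) for n in names})
    return PosteriorSummary(
        draws=draws,
        subject_mean=subject_mean,
        subject_sd=subject_sd,
        hyper_mean=hyper_mean,
        rhat=rhat,
        acceptance={"subject": float(acc_sub.mean()), "hyper": float(acc_hyp.mean())},
        warnings=warnings,
        c_max=c_max,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass
class ModelComparison:
    table: pd.DataFrame  # one row per variant: n_params, nll, aic, bic, n_obs

    @property
    def best_aic(self) -> str:
        return str(self.table.sort_values("aic").iloc[0]["variant"])

    @property
    def best_bic(self) -> str:
        return str(self.table.sort_values("bic").iloc[0]["variant"])


def compare_models(
    subjects: list[tuple],
    variants: tuple[str, ...] = ("shared_alpha", "split_alpha", "no_fpe"),
    c_max: float = C_MAX_DEFAULT,
    n_restarts: int = 3,
    seed: int = 0,
    count_hyperparams: bool = False,
) -> ModelComparison:
    """AIC/BIC comparison of model variants over identical trial sets.

    Per-subject point fits are summed: NLL is the total over subjects,
    k = (params per subject) * n_subjects, and n_obs for BIC is the total
    number of responded free-choice trials.  With ``count_hyperparams``
    the four parent-distribution parameters per subject-level parameter
    are added to k (both conventions are reported because either may be
    defended; the default counts subject-level parameters only).
    """
    if len(variants) < 2:
        raise ValueError("need at least two variants to compare")
    n_obs = 0
    for sched, choices in subjects:
        arrs = prepare_arrays(sched, choices)
        n_obs += int(np.sum((arrs["free"] == 1) & (arrs["chosen"] >= 0)))
    rows = []
    for variant in variants:
        names, _ = VARIANTS[variant]
        total_nll = 0.0
        for j, (sched, choices) in enumerate(subjects):
            _, nll = fit_subject(
                sched, choices, variant=variant, c_max=c_max, n_restarts=n_restarts,
                seed=seed + j,
            )
            total_nll += nll
        k = len(names) * len(subjects)
        if count_hyperparams:
            k += 2 * len(names)  # parent mean + sd per parameter
        rows.append(
            {
                "variant": variant,
                "n_params": k,
                "nll": total_nll,
                "aic": 2 * k + 2 * total_nll,
                "bic": k * np.log(n_obs) + 2 * total_nll,
                "n_obs": n_obs,
            }
        )
    return ModelComparison(table=pd.DataFrame(rows))
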