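"""RL model: softmax, delta-rule updates, traces, likelihood, agent simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transrev import rl_model as rl
from transrev import task_design as td


class TestSoftmax:
    def test_symmetry(self):
        for theta in (0.0, 1.0, 50.0):
            assert rl.softmax_prob(0.3, 0.3, theta) == pytest.approx(0.5)

    def test_zero_slope_is_chance(self):
        assert rl.softmax_prob(1.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_printed_formula_value(self):
        # theta = 2 (c = 1): P = e^2 / (e^2 + 1)
        assert rl.softmax_prob(1.0, 0.0, 2.0) == pytest.approx(np.e**2 / (np.e**2 + 1), abs=1e-12)

    def test_large_slope_stable(self):
        p = rl.softmax_prob(1.0, 0.0, 1e6)
        assert 0.0 <= p <= 1.0 and p == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rl.softmax_prob(np.nan, 0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ev1=st.floats(0, 1), ev2=st.floats(0, 1),
        c=st.floats(0, 5),
    )
    def test_probabilities_sum_to_one(self, ev1, ev2, c):
        theta = 3.0**c - 1.0
        p1 = rl.softmax_prob(ev1, ev2, theta)
        p2 = rl.softmax_prob(ev2, ev1, theta)
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)


class TestStepUpdate:
    def test_zero_error_leaves_value(self):
        p = rl.ModelParams(alpha=0.5, c=1.0)
        out = rl.step_update((0.0, 0.0), 0.5, 0, (0, 1), p)
        assert out["vpe"] == 0.0
        assert out["ev"][0] == 0.0

    def test_identity_update_from_initialisation(self):
        # EI starts at 0.5; sweet outcome with alpha = 0.5 moves it to 0.75
        p = rl.ModelParams(alpha=0.5, c=1.0)
        out = rl.step_update((0.0, 0.0), 0.5, 0, (0, 1), p)
        assert out["ipe"] == pytest.approx(0.5)
        assert out["ei"] == pytest.approx(0.75)

    def test_fictive_update(self):
        p = rl.ModelParams(alpha=0.5, c=1.0)
        out = rl.step_update((0.0, 0.8), 0.5, 0, (1, 0), p)
        assert out["fpe"] == pytest.approx(-0.8)
        assert out["ev"][1] == pytest.approx(0.4)

    def test_bad_outcome_rejected(self):
        p = rl.ModelParams(alpha=0.5, c=1.0)
        with pytest.raises(ValueError):
            rl.step_update((0.0, 0.0), 0.5, 0, (2, 1), p)


def _brute_force_nll(schedule, choices, alpha, theta):
    """Independent step-by-step trace oracle (pure python, no shared code)."""
    df = schedule.to_frame()
    ev = [0.0, 0.0]
    nll = 0.0
    for t in range(len(df)):
        c = int(choices[t])
        if c < 0:
            continue
        if df.loc[t, "choice_type"] == "free":
            import math

            p1 = math.exp(theta * ev[0]) / (math.exp(theta * ev[0]) + math.exp(theta * ev[1]))
            nll -= math.log(p1 if c == 0 else 1 - p1)
        v = 1.0 if c == int(df.loc[t, "high_cs"]) else 0.0
        ev[c] = ev[c] + alpha * (v - ev[c])
        ev[1 - c] = ev[1 - c] + alpha * ((1.0 - v) - ev[1 - c])
    return nll


class TestRunModel:
    def test_all_forced_has_zero_likelihood(self):
        s = td.generate_schedule(9, (9,), td.VREV, seed=0, forced_fraction=1.0)
        choices = s.to_frame()["forced_cs"].to_numpy()
        _, nll = rl.run_model(s, choices, rl.ModelParams(alpha=0.3, c=1.0))
        assert nll == 0.0

    def test_chance_model_nll(self, schedule84):
        df = schedule84.to_frame()
        choices = np.where(df["forced_cs"] >= 0, df["forced_cs"], 0).astype(int)
        n_free = (df["choice_type"] == "free").sum()
        _, nll = rl.run_model(schedule84, choices, rl.ModelParams(alpha=0.3, c=0.0))
        assert nll == pytest.approx(n_free * np.log(2), rel=1e-12)

    @pytest.mark.parametrize("alpha,c,seed", [(0.5, 1.0, 3), (0.2, 2.0, 4), (0.8, 0.5, 5)])
    def test_nll_matches_brute_force_oracle(self, alpha, c, seed):
        # short sessions so the oracle recursion stays hand-checkable
        s = td.generate_schedule(9, (9,), td.IREV, seed=seed)
        params = rl.ModelParams(alpha=alpha, c=c)
        choices, _ = rl.simulate_agent(s, params, seed=seed)
        _, nll = rl.run_model(s, choices, params)
        assert nll == pytest.approx(_brute_force_nll(s, choices, alpha, params.theta), abs=1e-10)

    def test_trace_invariants(self, three_runs):
        params = rl.ModelParams(alpha=0.4, c=1.5)
        choices, trace = rl.simulate_agent(three_runs, params, seed=1)
        assert np.allclose(trace["P_1"] + trace["P_2"], 1.0)
        for col in ("EV_1", "EV_2", "EI"):
            assert trace[col].between(0, 1).all()
        for col in ("iPE", "vPE", "fPE"):
            assert trace[col].dropna().between(-1, 1).all()
        assert abs(trace["iPE"].iloc[0]) == pytest.approx(0.5)  # EI initialised at 0.5

    def test_ev_sum_geometric_convergence(self, schedule84):
        # anti-correlated deterministic outcomes: EV_1 + EV_2 -> 1 as 1 - (1-a)^t
        alpha = 0.37
        df = schedule84.to_frame()
        choices = np.where(df["forced_cs"] >= 0, df["forced_cs"], 0).astype(int)
        trace, _ = rl.run_model(schedule84, choices, rl.ModelParams(alpha=alpha, c=1.0))
        evsum = (trace["EV_1"] + trace["EV_2"]).to_numpy()
        t = np.arange(len(evsum))
        assert np.allclose(evsum, 1 - (1 - alpha) ** t, atol=1e-12)

    def test_ipe_decay_and_jump_at_identity_reversal(self, schedule84):
        alpha = 0.5
        df = schedule84.to_frame()
        choices = np.where(df["forced_cs"] >= 0, df["forced_cs"], 0).astype(int)
        trace, _ = rl.run_model(schedule84, choices, rl.ModelParams(alpha=alpha, c=1.0))
        abs_ipe = trace["abs_iPE"].to_numpy()
        block = df["block"].to_numpy()
        within = block[1:] == block[:-1]
        # geometric decay with factor (1 - alpha) within blocks
        ratio = abs_ipe[1:][within] / np.where(abs_ipe[:-1][within] == 0, np.nan, abs_ipe[:-1][within])
        assert np.allclose(ratio[~np.isnan(ratio)], 1 - alpha, atol=1e-12)

    def test_pe_separation_after_convergence(self):
        # long converged blocks: vREV drives vPE but ~no iPE; iREV drives iPE
        # while the forced high->high transition carries ~no vPE
        s0 = td.TaskState("sweet", 0)
        states = [s0, td.apply_reversal(s0, td.VREV)]
        states.append(td.apply_reversal(states[-1], td.IREV))
        trials, revs = [], []
        idx = 0
        L = 20
        for b, st_ in enumerate(states):
            if b > 0:
                revs.append({"trial_index": idx, "kind": td.VREV if b == 1 else td.IREV})
            for p in range(L):
                forced = st_.high_cs if p % 2 == 0 else 1 - st_.high_cs
                trials.append(td.TrialSpec(idx, b, st_, "forced", forced))
                idx += 1
        sched = td.SessionSchedule(trials=trials, reversals=revs)
        df = sched.to_frame()
        choices = df["forced_cs"].to_numpy()
        trace, _ = rl.run_model(sched, choices, rl.ModelParams(alpha=0.5, c=1.0))
        t_vrev, t_irev = revs[0]["trial_index"], revs[1]["trial_index"]
        assert trace["abs_iPE"].iloc[t_vrev] < 1e-4  # identity unchanged at vREV
        assert abs(trace["vPE"].iloc[t_vrev]) > 0.9  # value flipped
        assert trace["abs_iPE"].iloc[t_irev] > 0.9  # identity flipped at iREV
        # first post-iREV trial choosing the (still) high CS: value matched
        assert abs(trace["vPE"].iloc[t_irev]) < 1e-4

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            rl.run_model([], np.array([]), rl.ModelParams(alpha=0.5, c=1.0))

    def test_choices_length_checked(self, schedule84):
        with pytest.raises(ValueError):
            rl.run_model(schedule84, np.zeros(10, dtype=int), rl.ModelParams(alpha=0.5, c=1.0))


class TestSimulateAgent:
    def test_forced_trials_follow_cue(self, schedule84):
        choices, _ = rl.simulate_agent(schedule84, rl.ModelParams(alpha=0.5, c=2.0), seed=0)
        df = schedule84.to_frame()
        forced = df["choice_type"] == "forced"
        assert np.array_equal(choices[forced], df.loc[forced, "forced_cs"])

    def test_chance_agent_near_half(self, three_runs):
        choices, trace = rl.simulate_agent(three_runs, rl.ModelParams(alpha=0.5, c=0.0), seed=2)
        free = trace["choice_type"] == "free"
        rate = (trace.loc[free, "chosen_cs"] == 0).mean()
        n = int(free.sum())
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_deterministic_agent_prefers_high(self):
        # theta >> 1 and long blocks: converged free choices are high-intensity
        s = td.generate_schedule(24, (12,), td.VREV, seed=3)
        choices, trace = rl.simulate_agent(s, rl.ModelParams(alpha=0.7, c=3.0), seed=4)
        df = s.to_frame()
        late = (df.index.to_numpy() % 12 >= 6) & (df["choice_type"] == "free").to_numpy()
        hit = choices[late] == df.loc[late, "high_cs"].to_numpy()
        assert hit.mean() == 1.0

    def test_reproducible_under_seed(self, three_runs):
        p = rl.ModelParams(alpha=0.4, c=1.0)
        c1, _ = rl.simulate_agent(three_runs, p, seed=9)
        c2, _ = rl.simulate_agent(three_runs, p, seed=9)
        assert np.array_equal(c1, c2)

    def test_missed_trials_flagged_and_skipped(self, schedule84):
        p = rl.ModelParams(alpha=0.4, c=1.0)
        choices, trace = rl.simulate_agent(schedule84, p, seed=5, miss_rate=0.2)
        missed = trace["responded"] == 0
        assert missed.sum() > 0
        assert trace.loc[missed, "iPE"].isna().all()
        assert (trace.loc[missed, "chosen_cs"] == -1).all()
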