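"""Task-state enumeration and session-schedule invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transrev import task_design as td


class TestStates:
    def test_four_unique_states(self):
        states = td.enumerate_states()
        assert len(states) == 4
        assert len({s.state_id for s in states}) == 4

    def test_both_cs_share_identity_and_oppose_intensity(self):
        for s in td.enumerate_states():
            us = s.cs_to_us
            assert us[0]["identity"] == us[1]["identity"]
            assert {us[0]["intensity"], us[1]["intensity"]} == {"high", "low"}

    def test_each_state_has_one_partner_per_relation(self):
        # exhaustive enumeration of the 2x2 design
        states = td.enumerate_states()
        for a in states:
            rels = [td.state_relation(a, b).value for b in states]
            assert sorted(rels) == ["DIDV", "DISV", "SIDV", "SISV"]

    def test_relation_examples(self):
        sweet_cs0 = td.TaskState("sweet", 0)
        savory_cs0 = td.TaskState("savory", 0)
        sweet_cs1 = td.TaskState("sweet", 1)
        assert td.state_relation(sweet_cs0, sweet_cs0) is td.StateRelation.SISV
        assert td.state_relation(sweet_cs0, savory_cs0) is td.StateRelation.DISV
        assert td.state_relation(sweet_cs0, sweet_cs1) is td.StateRelation.SIDV

    def test_reversals_map_to_relations(self):
        for s in td.enumerate_states():
            assert td.state_relation(s, td.apply_reversal(s, td.IREV)) is td.StateRelation.DISV
            assert td.state_relation(s, td.apply_reversal(s, td.VREV)) is td.StateRelation.SIDV

    def test_outcome_is_deterministic(self):
        s = td.TaskState("savory", 1)
        assert s.outcome(1) == (1, 0)
        assert s.outcome(0) == (0, 0)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            td.TaskState("sour", 0)
        with pytest.raises(ValueError):
            td.TaskState("sweet", 2)


class TestSchedule:
    def test_84_trial_structure(self, schedule84):
        s = schedule84
        df = s.to_frame()
        assert s.n_trials == 84
        assert s.n_blocks == 8
        lengths = df.groupby("block").size()
        assert sorted(lengths) == [9, 9, 9, 9, 12, 12, 12, 12]
        assert len(s.reversals) == 7

    def test_reversal_kinds_alternate(self, schedule84):
        kinds = [r["kind"] for r in schedule84.reversals]
        assert kinds[0] == td.VREV
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_consecutive_states_match_reversal_kind(self, schedule84):
        states = schedule84.block_states()
        for (a, b), rev in zip(zip(states, states[1:]), schedule84.reversals):
            rel = td.state_relation(a, b)
            expected = td.StateRelation.DISV if rev["kind"] == td.IREV else td.StateRelation.SIDV
            assert rel is expected

    def test_two_thirds_forced(self, schedule84):
        df = schedule84.to_frame()
        assert (df["choice_type"] == "forced").sum() == 56

    def test_blocks_open_with_two_forced_one_per_cs(self, schedule84):
        df = schedule84.to_frame()
        for _, block in df.groupby("block"):
            first_two = block.iloc[:2]
            assert list(first_two["choice_type"]) == ["forced", "forced"]
            assert sorted(first_two["forced_cs"]) == [0, 1]

    def test_reversals_on_forced_trials(self, schedule84):
        df = schedule84.to_frame().set_index("trial")
        for rev in schedule84.reversals:
            assert df.loc[rev["trial_index"], "choice_type"] == "forced"

    @pytest.mark.parametrize("seed", range(5))
    def test_balanced_block_mix_at_any_seed(self, seed):
        s = td.generate_schedule(84, (9, 12), td.VREV, seed=seed)
        lengths = sorted(s.to_frame().groupby("block").size())
        assert lengths == [9, 9, 9, 9, 12, 12, 12, 12]

    def test_single_block_no_reversals(self):
        s = td.generate_schedule(9, (9,), td.IREV, seed=0)
        assert s.n_blocks == 1
        assert s.reversals == []

    def test_infeasible_trial_count_raises(self):
        with pytest.raises(ValueError, match="sum of block lengths"):
            td.generate_schedule(10, (9, 12), td.VREV, seed=0)

    def test_reproducible_under_seed(self):
        a = td.generate_schedule(84, (9, 12), td.VREV, seed=7)
        b = td.generate_schedule(84, (9, 12), td.VREV, seed=7)
        assert a.to_frame().equals(b.to_frame())
        assert a.reversals == b.reversals
        c = td.generate_schedule(84, (9, 12), td.VREV, seed=8)
        assert not a.to_frame().equals(c.to_frame())

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        n_blocks=st.integers(min_value=1, max_value=8),
        first=st.sampled_from([td.IREV, td.VREV]),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_schedule_invariants_property(self, n_blocks, first, seed):
        # feasible by construction: mix of 9s and 12s
        n_trials = 9 * ((n_blocks + 1) // 2) + 12 * (n_blocks // 2)
        s = td.generate_schedule(n_trials, (9, 12), first, seed=seed)
        assert len(s.reversals) == s.n_blocks - 1
        kinds = [r["kind"] for r in s.reversals]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        states = s.block_states()
        for a, b in zip(states, states[1:]):
            assert td.state_relation(a, b) in (td.StateRelation.DISV, td.StateRelation.SIDV)
        if n_trials % 3 == 0:
            df = s.to_frame()
            assert (df["choice_type"] == "forced").sum() == round(2 * n_trials / 3)
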