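"""Task states and session schedules for the transreinforcer reversal-learning task.

The task pairs two conditioned stimuli (CS 0 and CS 1) with food-odor
outcomes (US) that vary on two orthogonal dimensions: identity
(sweet/savory) and intensity (high/low, the value dimension).  Within a
block both CSs predict the *same* odor identity and *opposite*
intensities, which yields exactly four possible CS-US association
mappings ("task states").  Blocks are separated by covert reversals that
change either the predicted identity (iREV) or the CS-value assignment
(vREV), strictly alternating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

SWEET = "sweet"
SAVORY = "savory"
HIGH = "high"
LOW = "low"

IREV = "iREV"
VREV = "vREV"


class StateRelation(str, Enum):
    """Relation between two task states: Same/Different Identity x Same/Different CS-Value mapping."""

    SISV = "SISV"
    SIDV = "SIDV"
    DISV = "DISV"
    DIDV = "DIDV"


@dataclass(frozen=True)
class TaskState:
    """One of the four CS-US association mappings.

    Parameters
    ----------
    identity : str
        Odor identity both CSs currently predict (``"sweet"`` or ``"savory"``).
    high_cs : int
        Which CS (0 or 1) is paired with the high-intensity US; the other
        CS receives the low-intensity US of the same identity.
    """

    identity: str
    high_cs: int

    def __post_init__(self) -> None:
        if self.identity not in (SWEET, SAVORY):
            raise ValueError(f"identity must be 'sweet' or 'savory', got {self.identity!r}")
        if self.high_cs not in (0, 1):
            raise ValueError(f"high_cs must be 0 or 1, got {self.high_cs!r}")

    @property
    def state_id(self) -> int:
        """Canonical index 0..3 (sweet before savory, CS0-high before CS1-high)."""
        return (0 if self.identity == SWEET else 2) + self.high_cs

    @property
    def cs_to_us(self) -> dict[int, dict[str, str]]:
        """Mapping CS label -> US descriptor {identity, intensity}."""
        return {
            cs: {"identity": self.identity, "intensity": HIGH if cs == self.high_cs else LOW}
            for cs in (0, 1)
        }

    def outcome(self, chosen_cs: int) -> tuple[int, int]:
        """Deterministic outcome of choosing ``chosen_cs``: (V, I).

        V = 1 for high intensity, 0 for low; I = 1 for sweet, 0 for savory.
        """
        if chosen_cs not in (0, 1):
            raise ValueError(f"chosen_cs must be 0 or 1, got {chosen_cs!r}")
        v = 1 if chosen_cs == self.high_cs else 0
        i = 1 if self.identity == SWEET else 0
        return v, i


def enumerate_states() -> list[TaskState]:
    """All four task states in canonical order.

    Both CSs always map to the same identity and opposite intensities, so
    the state space is identity (2) x which-CS-is-high (2) = 4.
    """
    return [TaskState(identity, high_cs) for identity in (SWEET, SAVORY) for high_cs in (0, 1)]


def state_relation(state_a: TaskState, state_b: TaskState) -> StateRelation:
    """Relation label between two states.

    Same identity (SI) iff the predicted odor identities match; same
    value (SV) iff the CS-to-intensity assignment matches.
    """
    si = state_a.identity == state_b.identity
    sv = state_a.high_cs == state_b.high_cs
    if si and sv:
        return StateRelation.SISV
    if si:
        return StateRelation.SIDV
    if sv:
        return StateRelation.DISV
    return StateRelation.DIDV


def apply_reversal(state: TaskState, kind: str) -> TaskState:
    """State after a reversal: iREV flips identity (value kept), vREV swaps the CS-value assignment."""
    if kind == IREV:
        return TaskState(SAVORY if state.identity == SWEET else SWEET, state.high_cs)
    if kind == VREV:
        return TaskState(state.identity, 1 - state.high_cs)
    raise ValueError(f"unknown reversal kind {kind!r}")


@dataclass(frozen=True)
class TrialSpec:
    index: int
    block: int
    state: TaskState
    choice_type: str  # "forced" | "free"
    forced_cs: int | None  # CS label on forced trials, None on free trials


@dataclass
class SessionSchedule:
    """Ordered trial list plus reversal bookkeeping for one run."""

    trials: list[TrialSpec]
    reversals: list[dict] = field(default_factory=list)  # {"trial_index", "kind"}

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_blocks(self) -> int:
        return self.trials[-1].block + 1 if self.trials else 0

    def block_states(self) -> list[TaskState]:
        states: list[TaskState] = []
        for t in self.trials:
            if t.block == len(states):
                states.append(t.state)
        return states

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per trial); simulation columns left blank."""
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "trial": t.index,
                    "block": t.block,
                    "state_id": t.state.state_id,
                    "identity": t.state.identity,
                    "high_cs": t.state.high_cs,
                    "choice_type": t.choice_type,
                    "forced_cs": t.forced_cs if t.forced_cs is not None else -1,
                }
            )
        return pd.DataFrame(rows)


def _block_lengths_for(n_trials: int, allowed: tuple[int, ...], rng: np.random.Generator) -> list[int]:
    """Multiset of block lengths from ``allowed`` summing to ``n_trials``, order shuffled.

    When several length-multisets fit, the most balanced one is used
    (smallest spread of per-length counts: 84 trials with lengths {9, 12}
    gives four of each, matching the session design); remaining ties are
    broken by the seeded generator.
    """
    allowed = tuple(sorted(set(allowed)))
    solutions: list[list[int]] = []

    def rec(remaining: int, idx: int, counts: list[int]) -> None:
        if idx == len(allowed):
            if remaining == 0:
                solutions.append(list(counts))
            return
        length = allowed[idx]
        for k in range(remaining // length + 1):
            counts.append(k)
            rec(remaining - k * length, idx + 1, counts)
            counts.pop()

    rec(n_trials, 0, [])
    if not solutions:
        raise ValueError(
            f"n_trials={n_trials} cannot be written as a sum of block lengths from {allowed}"
        )
    spread = [max(c) - min(c) for c in solutions]
    best = [c for c, s in zip(solutions, spread) if s == min(spread)]
    counts = best[rng.integers(len(best))]
    lengths = [L for L, k in zip(allowed, counts) for _ in range(k)]
    rng.shuffle(lengths)
    return lengths


def generate_schedule(
    n_trials: int = 84,
    block_lengths: tuple[int, ...] = (9, 12),
    first_reversal_kind: str = VREV,
    seed: int = 0,
    forced_fraction: float = 2.0 / 3.0,
    start_state: TaskState | None = None,
) -> SessionSchedule:
    """Generate one pseudorandomized session schedule.

    Constraints honoured exactly:

    * blocks are contiguous with lengths drawn from ``block_lengths``;
    * reversal kinds strictly alternate, starting with ``first_reversal_kind``;
    * every block opens with two forced-choice trials, one per CS, in
      random order (so reversals always land on forced trials);
    * ``round(forced_fraction * n_trials)`` trials are forced overall,
      with the extra forced trials placed uniformly at random among the
      non-opening positions.

    Deterministic for a fixed ``seed``.
    """
    if first_reversal_kind not in (IREV, VREV):
        raise ValueError(f"first_reversal_kind must be {IREV!r} or {VREV!r}")
    rng = np.random.default_rng(seed)
    lengths = _block_lengths_for(n_trials, tuple(block_lengths), rng)
    n_blocks = len(lengths)
    if min(lengths) < 2:
        raise ValueError("block lengths must be >= 2 to fit the two forced opening trials")

    if start_state is None:
        start_state = enumerate_states()[rng.integers(4)]
    states = [start_state]
    kind = first_reversal_kind
    kinds: list[str] = []
    for _ in range(n_blocks - 1):
        states.append(apply_reversal(states[-1], kind))
        kinds.append(kind)
        kind = IREV if kind == VREV else VREV

    n_forced = int(round(forced_fraction * n_trials))
    n_opening = 2 * n_blocks
    if n_forced < n_opening:
        raise ValueError(
            f"forced_fraction gives {n_forced} forced trials but {n_opening} block-opening "
            "trials are forced by design"
        )
    # place the remaining forced trials uniformly among non-opening positions
    non_opening: list[tuple[int, int]] = []  # (block, within-block position)
    for b, L in enumerate(lengths):
        for p in range(2, L):
            non_opening.append((b, p))
    extra = rng.choice(len(non_opening), size=n_forced - n_opening, replace=False)
    extra_forced = {non_opening[i] for i in extra}

    trials: list[TrialSpec] = []
    reversals: list[dict] = []
    idx = 0
    for b, L in enumerate(lengths):
        if b > 0:
            reversals.append({"trial_index": idx, "kind": kinds[b - 1]})
        opening = [0, 1]
        rng.shuffle(opening)
        for p in range(L):
            if p < 2:
                trials.append(TrialSpec(idx, b, states[b], "forced", int(opening[p])))
            elif (b, p) in extra_forced:
                trials.append(TrialSpec(idx, b, states[b], "forced", int(rng.integers(2))))
            else:
                trials.append(TrialSpec(idx, b, states[b], "free", None))
            idx += 1
    return SessionSchedule(trials=trials, reversals=reversals)
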