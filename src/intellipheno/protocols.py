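"""Task-controller logic for each testing phase.

Three pieces live here:

* the per-phase door policy (when the motorized doors in front of the
  waterspouts open) and the airpuff contingency of the avoidance phase;
* the serial-reaction-time (SRT) trial state machine, used both to drive
  the simulated controller and to re-derive trial outcomes from recorded
  nosepoke streams;
* the reward-corner assignment algorithm for the place-preference phase
  (least-visited corner, capacity four per corner, per-corner genotype
  balance) and the diagonal reversal mapping.

SRT timing: the first nosepoke of a visit to the assigned corner initiates
a trial; a 2 s pre-cue delay precedes a 7 s LED cue.  A poke during the
delay is *premature*, a poke during the cue is *correct* (reaction time =
latency from cue onset), and cue timeout with no poke is *incorrect*.  Any
terminal outcome locks the machine until the animal exits the corner, so a
visit yields at most one trial.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .event_model import CORNERS, Phase

PRECUE_DELAY_S = 2.0
CUE_DURATION_S = 7.0
TRIAL_SPAN_S = PRECUE_DELAY_S + CUE_DURATION_S  # 9 s from initiation to timeout
AIRPUFF_BAR = 0.8
AIRPUFF_DURATION_S = 1.0


class DoorPolicy(str, enum.Enum):
    ALWAYS_OPEN = "always_open"
    OPEN_ON_VISIT = "open_on_visit"
    OPEN_ON_NOSEPOKE_ANY_CORNER = "open_on_nosepoke_any_corner"
    OPEN_ON_NOSEPOKE_CORRECT_CORNER = "open_on_nosepoke_correct_corner"
    OPEN_ON_CORRECT_SRT_RESPONSE = "open_on_correct_srt_response"
    CLOSED = "closed"


class DoorAction(str, enum.Enum):
    OPEN = "open"
    STAY_CLOSED = "stay_closed"


class EventKind(str, enum.Enum):
    VISIT_ENTRY = "visit_entry"
    NOSEPOKE = "nosepoke"
    SRT_CORRECT = "srt_correct"


_PHASE_POLICY: dict[Phase, DoorPolicy] = {
    Phase.FREE_ADAPT: DoorPolicy.ALWAYS_OPEN,
    Phase.DOOR_ADAPT: DoorPolicy.OPEN_ON_VISIT,
    Phase.NOSEPOKE_ADAPT: DoorPolicy.OPEN_ON_NOSEPOKE_ANY_CORNER,
    Phase.PLACE_PREF: DoorPolicy.OPEN_ON_NOSEPOKE_CORRECT_CORNER,
    Phase.REVERSAL: DoorPolicy.OPEN_ON_NOSEPOKE_CORRECT_CORNER,
    Phase.SRT: DoorPolicy.OPEN_ON_CORRECT_SRT_RESPONSE,
    Phase.AVOIDANCE: DoorPolicy.CLOSED,  # no water during learned avoidance
    Phase.DELAY_OFFCAGE: DoorPolicy.CLOSED,
    Phase.RETENTION: DoorPolicy.OPEN_ON_NOSEPOKE_ANY_CORNER,
}


@dataclass(frozen=True)
class ControllerRule:
    """Door/water/airpuff contingency active during one phase.

    ``water_corners`` maps animal -> reward corner for the per-animal phases
    (place preference, reversal, SRT); ``airpuff_corner`` maps animal ->
    punished corner during the avoidance phase.
    """

    phase: Phase
    door_policy: DoorPolicy
    water_corners: Mapping[str, int] | None = None
    airpuff_corner: Mapping[str, int] | None = None


def rule_for_phase(
    phase: Phase | str,
    assignment: Mapping[str, int] | None = None,
) -> ControllerRule:
    """The controller rule of ``phase``; per-animal phases need ``assignment``."""
    phase = Phase(phase)
    policy = _PHASE_POLICY[phase]
    water = None
    puff = None
    if policy in (DoorPolicy.OPEN_ON_NOSEPOKE_CORRECT_CORNER, DoorPolicy.OPEN_ON_CORRECT_SRT_RESPONSE):
        if assignment is None:
            raise ValueError(f"phase {phase.value!r} needs a corner assignment")
        water = dict(assignment)
    if phase is Phase.AVOIDANCE:
        if assignment is None:
            raise ValueError("avoidance phase needs the per-animal airpuff corner")
        puff = dict(assignment)
    return ControllerRule(phase, policy, water, puff)


def door_action(
    rule: ControllerRule,
    animal_id: str,
    corner: int,
    event: EventKind | str,
) -> DoorAction:
    """Whether the door opens for ``event`` by ``animal_id`` at ``corner``.

    Pure function of (rule, event kind, corner match); no hidden state.  SRT
    correctness is decided by the trial machine, which feeds an
    ``srt_correct`` event here.
    """
    event = EventKind(event)
    policy = rule.door_policy
    if policy is DoorPolicy.CLOSED:
        return DoorAction.STAY_CLOSED
    if policy is DoorPolicy.ALWAYS_OPEN:
        return DoorAction.OPEN
    if policy is DoorPolicy.OPEN_ON_VISIT:
        return DoorAction.OPEN if event is EventKind.VISIT_ENTRY else DoorAction.STAY_CLOSED
    if policy is DoorPolicy.OPEN_ON_NOSEPOKE_ANY_CORNER:
        return DoorAction.OPEN if event is EventKind.NOSEPOKE else DoorAction.STAY_CLOSED
    if policy is DoorPolicy.OPEN_ON_NOSEPOKE_CORRECT_CORNER:
        if event is EventKind.NOSEPOKE and rule.water_corners is not None:
            if rule.water_corners.get(animal_id) == corner:
                return DoorAction.OPEN
        return DoorAction.STAY_CLOSED
    # OPEN_ON_CORRECT_SRT_RESPONSE
    if event is EventKind.SRT_CORRECT and rule.water_corners is not None:
        if rule.water_corners.get(animal_id) == corner:
            return DoorAction.OPEN
    return DoorAction.STAY_CLOSED


def airpuff_triggered(
    airpuff_corner: Mapping[str, int], animal_id: str, corner: int, is_nosepoke: bool
) -> bool:
    """True iff a *nosepoke* lands in the animal's punished corner.

    Visits without a nosepoke never trigger the puff.
    """
    return bool(is_nosepoke) and airpuff_corner.get(animal_id) == corner


# ---------------------------------------------------------------------------
# SRT trial state machine
# ---------------------------------------------------------------------------

class SRTState(str, enum.Enum):
    IDLE = "idle"
    PRECUE = "precue"
    CUE = "cue"
    LOCKED_UNTIL_EXIT = "locked_until_exit"


class TrialOutcome(str, enum.Enum):
    CORRECT = "correct"
    PREMATURE = "premature"
    INCORRECT = "incorrect"


@dataclass(frozen=True)
class SRTTrialState:
    state: SRTState = SRTState.IDLE
    t_init: float | None = None
    t_last: float = float("-inf")

    @property
    def t_cue_on(self) -> float | None:
        return None if self.t_init is None else self.t_init + PRECUE_DELAY_S


@dataclass(frozen=True)
class TrialRecord:
    """One reconstructed SRT trial."""

    animal_id: str
    day_index: int
    t_init: float
    outcome: TrialOutcome
    reaction_time: float | None = None  # present iff correct; within [0, 7]


def srt_step(
    state: SRTTrialState,
    event: tuple[str, float],
) -> tuple[SRTTrialState, TrialOutcome | None, float | None]:
    """Advance the trial machine by one event.

    ``event`` is ``(kind, t)`` with kind one of ``"nosepoke"``,
    ``"corner_exit"``, ``"clock"`` (pure time advance).  Returns the new
    state plus, when a trial terminates on this event, its outcome and (for
    correct trials) the reaction time measured from cue onset.

    Events must be fed in non-decreasing time order.
    """
    kind, t = event
    if t < state.t_last:
        raise ValueError(f"out-of-order event at t={t} (last seen {state.t_last})")
    state = replace(state, t_last=t)

    if kind not in ("nosepoke", "corner_exit", "clock"):
        raise ValueError(f"unknown event kind {kind!r}")

    if state.state is SRTState.LOCKED_UNTIL_EXIT:
        # extra pokes while locked are outside-trial; exit re-arms the machine
        if kind == "corner_exit":
            return replace(state, state=SRTState.IDLE, t_init=None), None, None
        return state, None, None

    if state.state is SRTState.IDLE:
        if kind == "nosepoke":
            return replace(state, state=SRTState.PRECUE, t_init=t), None, None
        return state, None, None

    # trial in progress (PRECUE or CUE)
    t_init = state.t_init
    assert t_init is not None
    t_cue = t_init + PRECUE_DELAY_S
    t_timeout = t_init + TRIAL_SPAN_S

    # time passing alone resolves an un-answered cue as incorrect;
    # the LED timer runs regardless of whether the animal is still inside,
    # so an early exit also resolves as incorrect
    if kind in ("clock", "corner_exit"):
        if t >= t_timeout or kind == "corner_exit":
            new = SRTState.IDLE if kind == "corner_exit" else SRTState.LOCKED_UNTIL_EXIT
            return replace(state, state=new, t_init=None), TrialOutcome.INCORRECT, None
        # clock before timeout: just advance (possibly into the cue window)
        new = SRTState.CUE if t >= t_cue else SRTState.PRECUE
        return replace(state, state=new), None, None

    # nosepoke during a trial
    if t < t_cue:
        return (
            replace(state, state=SRTState.LOCKED_UNTIL_EXIT, t_init=None),
            TrialOutcome.PREMATURE,
            None,
        )
    if t <= t_timeout:
        return (
            replace(state, state=SRTState.LOCKED_UNTIL_EXIT, t_init=None),
            TrialOutcome.CORRECT,
            t - t_cue,
        )
    # poke after the cue expired: the timeout already decided the trial
    return (
        replace(state, state=SRTState.LOCKED_UNTIL_EXIT, t_init=None),
        TrialOutcome.INCORRECT,
        None,
    )


def classify_visit_trial(
    poke_times: Sequence[float], t_exit: float
) -> tuple[TrialOutcome, float, float | None] | None:
    """Classify the (at most one) trial of a single assigned-corner visit.

    ``poke_times`` are the visit's nosepoke timestamps in order; ``t_exit``
    is the corner exit time.  Returns ``(outcome, t_init, reaction_time)``
    or ``None`` when the visit had no nosepoke (no trial initiated).
    """
    state = SRTTrialState()
    result: tuple[TrialOutcome, float, float | None] | None = None
    t_init: float | None = None
    for t in poke_times:
        if state.state is SRTState.IDLE and result is None:
            t_init = t
        state, outcome, rt = srt_step(state, ("nosepoke", t))
        if outcome is not None and result is None:
            result = (outcome, float(t_init), rt)  # type: ignore[arg-type]
    if result is None and state.state in (SRTState.PRECUE, SRTState.CUE):
        # resolve by timeout clock (runs past the exit if needed)
        t_final = max(t_exit, (t_init or t_exit) + TRIAL_SPAN_S)
        state, outcome, rt = srt_step(state, ("clock", t_final))
        if outcome is not None:
            result = (outcome, float(t_init), rt)  # type: ignore[arg-type]
    return result


# ---------------------------------------------------------------------------
# reward-corner assignment
# ---------------------------------------------------------------------------

def reversal_corner(corner: int) -> int:
    """Diagonally opposite corner under clockwise 1-4 indexing; involution."""
    if corner not in CORNERS:
        raise ValueError(f"corner {corner} outside 1-4")
    return ((corner + 1) % 4) + 1


class AssignmentError(ValueError):
    """No corner assignment satisfies the capacity/balance constraints."""


def _completable(
    counts: list[tuple[int, int]],
    remaining: tuple[int, int],
    max_per_corner: int,
    max_imbalance: int,
) -> bool:
    """Can ``remaining`` (n_nontg, n_tg) unassigned animals still be placed so
    every corner ends with ``<= max_per_corner`` animals and genotype
    difference ``<= max_imbalance``?  Small exact DP over corners."""
    states = {remaining}
    for a0, b0 in counts:  # a = NonTg, b = TG already at this corner
        nxt: set[tuple[int, int]] = set()
        cap = max_per_corner - a0 - b0
        for ra, rb in states:
            for da in range(0, min(ra, cap) + 1):
                for db in range(0, min(rb, cap - da) + 1):
                    if abs((a0 + da) - (b0 + db)) <= max_imbalance:
                        nxt.add((ra - da, rb - db))
        states = nxt
        if not states:
            return False
    return (0, 0) in states


def assign_corners(
    visit_counts: Mapping[str, Sequence[int]],
    genotypes: Mapping[str, str],
    max_per_corner: int = 4,
    max_imbalance: int = 1,
) -> dict[str, int]:
    """Assign each animal a reward corner among its *least-visited* corners.

    Constraints: at most ``max_per_corner`` animals per corner and per-corner
    genotype counts differing by at most ``max_imbalance`` (the 50-50
    balancing that prevents overcrowding and learning by imitation).
    Deterministic: animals are processed in ascending id; each takes the
    lowest-index corner in its preference order (fewest prior visits first)
    whose choice still leaves the remaining animals placeable — the
    fall-back to next-least-visited corners happens only when forced.
    """
    animals = sorted(visit_counts)
    if len(animals) > 4 * max_per_corner:
        raise AssignmentError(
            f"{len(animals)} animals exceed total capacity {4 * max_per_corner}"
        )
    for a in animals:
        if genotypes.get(a) not in ("NonTg", "TG"):
            raise AssignmentError(f"animal {a!r}: missing or unknown genotype")
        if len(visit_counts[a]) != 4:
            raise AssignmentError(f"animal {a!r}: need 4 per-corner visit counts")

    placed: list[tuple[int, int]] = [(0, 0)] * 4  # (NonTg, TG) per corner
    remaining = [
        sum(genotypes[a] == "NonTg" for a in animals),
        sum(genotypes[a] == "TG" for a in animals),
    ]
    if not _completable(placed, (remaining[0], remaining[1]), max_per_corner, max_imbalance):
        raise AssignmentError(
            "infeasible: genotype totals cannot satisfy per-corner balance"
        )

    assignment: dict[str, int] = {}
    for a in animals:
        gi = 0 if genotypes[a] == "NonTg" else 1
        order = sorted(CORNERS, key=lambda c: (visit_counts[a][c - 1], c))
        chosen = None
        for corner in order:
            i = corner - 1
            if placed[i][0] + placed[i][1] >= max_per_corner:
                continue
            trial = list(placed)
            trial[i] = (placed[i][0] + (gi == 0), placed[i][1] + (gi == 1))
            rem = (remaining[0] - (gi == 0), remaining[1] - (gi == 1))
            if _completable(trial, rem, max_per_corner, max_imbalance):
                placed = trial
                remaining[gi] -= 1
                chosen = corner
                break
        if chosen is None:
            raise AssignmentError(f"infeasible: no corner available for animal {a!r}")
        assignment[a] = chosen
    return assignment
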