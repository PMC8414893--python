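"""Per-animal, per-24-h-day dependent variables of each testing phase.

Denominator conventions (all percentages are 0-100):

* days on which a percentage's denominator is zero yield a *missing* value
  (``NaN``) rather than 0 — a zero would fabricate a behavioral score;
* place-preference correctness is decided by corner identity alone at the
  visit level (a door needs a nosepoke to open, but the score counts
  visits);
* SRT outcome percentages are taken over *initiated trials*, so
  correct + incorrect + premature = 100 exactly; trial initiation counts at
  most one trial per visit (the first nosepoke of an assigned-corner visit
  initiates it);
* the adaptation pass/fail rule mirrors the live protocol: a 24-h window
  with zero licks triggers removal, a second consecutive zero-lick window
  after reintroduction excludes the animal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import protocols
from .event_model import (
    ADAPTATION_PHASES,
    DayWindow,
    EventStore,
    Phase,
    animal_window_visits,
    slice_days,
)
from .protocols import TrialOutcome, TrialRecord


class FailureReason(str, enum.Enum):
    NONE = "none"
    NO_LICKS_TWICE = "no_licks_twice"


@dataclass(frozen=True)
class AdaptationOutcome:
    animal_id: str
    passed: bool
    failure_day: int | None = None  # 1-based index over the 9 adaptation days
    reason: FailureReason = FailureReason.NONE

    def __post_init__(self) -> None:
        assert self.passed == (self.failure_day is None)


# ---------------------------------------------------------------------------
# elementary per-window counts
# ---------------------------------------------------------------------------

def total_visits(store: EventStore, animal_id: str, window: DayWindow) -> int:
    """Number of visits attributed to the window (entry-time rule)."""
    return int(len(animal_window_visits(store, animal_id, window)["t_start"]))


def total_licks(store: EventStore, animal_id: str, window: DayWindow) -> int:
    """Licks over the window's visits (water-consumption measure)."""
    return int(animal_window_visits(store, animal_id, window)["n_licks"].sum())


def visits_with_nosepoke(store: EventStore, animal_id: str, window: DayWindow) -> int:
    """Visits containing at least one nosepoke (operant-learning measure)."""
    f = animal_window_visits(store, animal_id, window)
    return int((f["n_pokes"] > 0).sum())


def drink_motivated_fraction(store: EventStore, animal_id: str, window: DayWindow) -> float:
    """100 x (visits with >=1 lick) / (total visits): the share of corner
    entries driven by water-seeking rather than exploration.  NaN when the
    animal made no visits."""
    f = animal_window_visits(store, animal_id, window)
    n = len(f["t_start"])
    if n == 0:
        return float("nan")
    return 100.0 * float((f["n_licks"] > 0).sum()) / n


def pct_correct_place(
    store: EventStore, animal_id: str, window: DayWindow, assigned_corner: int
) -> float:
    """100 x (visits to the assigned corner) / (total visits); visit-level,
    corner identity alone.  NaN when the animal made no visits."""
    f = animal_window_visits(store, animal_id, window)
    n = len(f["t_start"])
    if n == 0:
        return float("nan")
    return 100.0 * float((f["corner"] == assigned_corner).sum()) / n


def correct_visit_with_lick(
    store: EventStore, animal_id: str, window: DayWindow, assigned_corner: int
) -> float:
    """100 x (assigned-corner visits with >=1 nosepoke and >=1 lick) /
    (assigned-corner visits).  NaN when there were no assigned-corner visits."""
    f = animal_window_visits(store, animal_id, window)
    correct = f["corner"] == assigned_corner
    n = int(correct.sum())
    if n == 0:
        return float("nan")
    hit = correct & (f["n_pokes"] > 0) & (f["n_licks"] > 0)
    return 100.0 * float(hit.sum()) / n


# ---------------------------------------------------------------------------
# SRT trial reconstruction and metrics
# ---------------------------------------------------------------------------

def _poke_times_by_visit(store: EventStore) -> dict[int, np.ndarray]:
    cached = store._cache.get("poke_times")
    if cached is None:
        pokes = store.nosepokes.sort_values("t", kind="mergesort")
        cached = {
            int(vid): sub["t"].to_numpy(float)
            for vid, sub in pokes.groupby("visit_id", sort=False)
        }
        store._cache["poke_times"] = cached
    return cached


def reconstruct_trials(
    store: EventStore, animal_id: str, window: DayWindow, assigned_corner: int
) -> list[TrialRecord]:
    """Re-derive the window's SRT trials from the recorded nosepoke stream.

    Each assigned-corner visit with at least one nosepoke initiates exactly
    one trial, classified by the controller state machine.
    """
    f = animal_window_visits(store, animal_id, window)
    pokes = _poke_times_by_visit(store)
    records: list[TrialRecord] = []
    for vid, corner, t_end in zip(f["visit_id"], f["corner"], f["t_end"]):
        if corner != assigned_corner:
            continue
        times = pokes.get(int(vid))
        if times is None or len(times) == 0:
            continue
        result = protocols.classify_visit_trial(list(times), float(t_end))
        if result is None:
            continue
        outcome, t_init, rt = result
        records.append(
            TrialRecord(animal_id, window.day_index, t_init, outcome, rt)
        )
    return records


def srt_metrics(
    trials: list[TrialRecord], n_total_visits: int
) -> dict[str, float]:
    """Percent initiated / correct / incorrect / premature and mean reaction
    time for one animal-day.

    ``pct_initiated`` is over all corner visits of the day; the outcome
    percentages are over initiated trials and partition 100%.  All are NaN
    when no trial was initiated (``pct_initiated`` needs visits > 0).
    """
    n_init = len(trials)
    nan = float("nan")
    out = {
        "pct_initiated": 100.0 * n_init / n_total_visits if n_total_visits > 0 else nan,
        "pct_correct": nan,
        "pct_incorrect": nan,
        "pct_premature": nan,
        "mean_reaction_time": nan,
    }
    if n_init == 0:
        return out
    n_correct = sum(t.outcome is TrialOutcome.CORRECT for t in trials)
    n_incorrect = sum(t.outcome is TrialOutcome.INCORRECT for t in trials)
    n_premature = sum(t.outcome is TrialOutcome.PREMATURE for t in trials)
    out["pct_correct"] = 100.0 * n_correct / n_init
    out["pct_incorrect"] = 100.0 * n_incorrect / n_init
    out["pct_premature"] = 100.0 * n_premature / n_init
    rts = [t.reaction_time for t in trials if t.reaction_time is not None]
    if rts:
        out["mean_reaction_time"] = float(np.mean(rts))
    return out


def all_srt_trials(store: EventStore) -> list[TrialRecord]:
    """Every reconstructed SRT trial of the cohort, in roster/day order."""
    assignment = store.corner_assignment(Phase.SRT)
    trials: list[TrialRecord] = []
    for animal_id, corner in sorted(assignment.items()):
        for window in slice_days(store, Phase.SRT):
            trials.extend(reconstruct_trials(store, animal_id, window, corner))
    return trials


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [t.animal_id for t in trials],
            "day": [t.day_index for t in trials],
            "t_init": [t.t_init for t in trials],
            "outcome": [t.outcome.value for t in trials],
            "reaction_time": [t.reaction_time for t in trials],
        }
    )


# ---------------------------------------------------------------------------
# avoidance and retention
# ---------------------------------------------------------------------------

def avoidance_metrics(
    store: EventStore, animal_id: str, airpuff_corner: int
) -> dict[str, int]:
    """Counts over the single 24-h learned-avoidance window: total visits and
    visits to the airpuff corner carrying a nosepoke (working-memory errors)."""
    window = slice_days(store, Phase.AVOIDANCE)[0]
    f = animal_window_visits(store, animal_id, window)
    err = (f["corner"] == airpuff_corner) & (f["n_pokes"] > 0)
    return {
        "total_visits_24h": int(len(f["t_start"])),
        "airpuff_nosepoke_visits": int(err.sum()),
    }


def retention_error_pct(
    store: EventStore, animal_id: str, former_airpuff_corner: int, window: DayWindow
) -> float:
    """100 x (visits to the former airpuff corner with >=1 nosepoke) /
    (total visits) for one retention day; NaN when the animal made no visits."""
    f = animal_window_visits(store, animal_id, window)
    n = len(f["t_start"])
    if n == 0:
        return float("nan")
    err = (f["corner"] == former_airpuff_corner) & (f["n_pokes"] > 0)
    return 100.0 * float(err.sum()) / n


# ---------------------------------------------------------------------------
# adaptation pass/fail and the pass-rate summary
# ---------------------------------------------------------------------------

def adaptation_windows(store: EventStore) -> list[DayWindow]:
    windows: list[DayWindow] = []
    for phase in ADAPTATION_PHASES:
        windows.extend(slice_days(store, phase))
    return windows


def pass_fail_adaptation(store: EventStore) -> list[AdaptationOutcome]:
    """Apply the removal rule over the nine adaptation days.

    A zero-lick 24-h window flags the animal for removal (7 h in a standard
    cage); a second zero-lick window immediately after reintroduction
    excludes it from the experiment.  A licking day clears the flag.
    """
    windows = adaptation_windows(store)
    outcomes: list[AdaptationOutcome] = []
    for animal_id in sorted(store.animals["animal_id"]):
        strike = False
        failure_day: int | None = None
        for k, window in enumerate(windows, start=1):
            if total_licks(store, animal_id, window) == 0:
                if strike:
                    failure_day = k
                    break
                strike = True
            else:
                strike = False
        if failure_day is None:
            outcomes.append(AdaptationOutcome(animal_id, True))
        else:
            outcomes.append(
                AdaptationOutcome(animal_id, False, failure_day, FailureReason.NO_LICKS_TWICE)
            )
    return outcomes


def percent_passed(n_started: int, n_passed: int) -> float:
    """100 x n_passed / n_started, reported to two decimals."""
    if n_started <= 0:
        raise ValueError("n_started must be positive")
    if not 0 <= n_passed <= n_started:
        raise ValueError("need 0 <= n_passed <= n_started")
    return round(100.0 * n_passed / n_started, 2)


def pass_summary(store: EventStore) -> pd.DataFrame:
    """Per-genotype roster-style summary: started, passed, percent passed."""
    outcomes = {o.animal_id: o.passed for o in pass_fail_adaptation(store)}
    rows = []
    for genotype, sub in store.animals.groupby("genotype"):
        ids = list(sub["animal_id"])
        n_started = len(ids)
        n_passed = sum(outcomes[a] for a in ids)
        rows.append(
            {
                "genotype": genotype,
                "n_started": n_started,
                "n_passed": n_passed,
                "pct_passed": percent_passed(n_started, n_passed),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the combined long-format metric table
# ---------------------------------------------------------------------------

#: metrics computed for each phase (besides the single-window avoidance set)
PHASE_METRICS: dict[Phase, tuple[str, ...]] = {
    Phase.FREE_ADAPT: ("total_visits", "total_licks"),
    Phase.DOOR_ADAPT: ("total_visits", "total_licks"),
    Phase.NOSEPOKE_ADAPT: (
        "total_visits",
        "total_licks",
        "visits_with_nosepoke",
        "drink_motivated_fraction",
    ),
    Phase.PLACE_PREF: (
        "total_visits",
        "total_licks",
        "pct_correct",
        "correct_visit_with_lick",
    ),
    Phase.REVERSAL: (
        "total_visits",
        "total_licks",
        "pct_correct",
        "correct_visit_with_lick",
    ),
    Phase.SRT: (
        "total_visits",
        "total_licks",
        "pct_initiated",
        "pct_correct",
        "pct_incorrect",
        "pct_premature",
        "mean_reaction_time",
    ),
    Phase.AVOIDANCE: ("total_visits", "airpuff_nosepoke_visits"),
    Phase.RETENTION: ("total_visits", "retention_error_pct"),
}


def compute_metrics(store: EventStore) -> pd.DataFrame:
    """Every in-scope dependent variable for every active animal-day.

    Returns a long-format frame with columns
    ``phase, metric, animal_id, genotype, day, value``.  Animals excluded
    during adaptation contribute adaptation days up to their exclusion day
    and nothing afterwards; post-adaptation per-animal phases cover only
    animals with a corner assignment.
    """
    outcomes = {o.animal_id: o for o in pass_fail_adaptation(store)}
    genotype = dict(zip(store.animals["animal_id"], store.animals["genotype"]))
    rows: list[tuple] = []

    def emit(phase: Phase, metric: str, animal_id: str, day: int, value: float) -> None:
        rows.append((phase.value, metric, animal_id, genotype[animal_id], day, value))

    adapt_day0 = {}  # global adaptation day offset per phase
    offset = 0
    for phase in ADAPTATION_PHASES:
        adapt_day0[phase] = offset
        offset += store.phase_span(phase).duration_days

    for phase, metric_names in PHASE_METRICS.items():
        if phase not in {s.phase for s in store.schedule}:
            continue
        windows = slice_days(store, phase)
        if phase in ADAPTATION_PHASES:
            for animal_id, outcome in outcomes.items():
                for window in windows:
                    global_day = adapt_day0[phase] + window.day_index
                    if not outcome.passed and global_day > outcome.failure_day:
                        continue
                    for m in metric_names:
                        if m == "total_visits":
                            v = total_visits(store, animal_id, window)
                        elif m == "total_licks":
                            v = total_licks(store, animal_id, window)
                        elif m == "visits_with_nosepoke":
                            v = visits_with_nosepoke(store, animal_id, window)
                        else:
                            v = drink_motivated_fraction(store, animal_id, window)
                        emit(phase, m, animal_id, window.day_index, float(v))
            continue

        assignment = store.corner_assignment(phase)
        for animal_id, corner in sorted(assignment.items()):
            if animal_id in outcomes and not outcomes[animal_id].passed:
                continue
            if phase is Phase.AVOIDANCE:
                counts = avoidance_metrics(store, animal_id, corner)
                emit(phase, "total_visits", animal_id, 1, float(counts["total_visits_24h"]))
                emit(phase, "airpuff_nosepoke_visits", animal_id, 1,
                     float(counts["airpuff_nosepoke_visits"]))
                continue
            for window in windows:
                nv = total_visits(store, animal_id, window)
                if phase is Phase.SRT:
                    trials = reconstruct_trials(store, animal_id, window, corner)
                    vals = srt_metrics(trials, nv)
                    emit(phase, "total_visits", animal_id, window.day_index, float(nv))
                    emit(phase, "total_licks", animal_id, window.day_index,
                         float(total_licks(store, animal_id, window)))
                    for m in ("pct_initiated", "pct_correct", "pct_incorrect",
                              "pct_premature", "mean_reaction_time"):
                        emit(phase, m, animal_id, window.day_index, vals[m])
                elif phase is Phase.RETENTION:
                    emit(phase, "total_visits", animal_id, window.day_index, float(nv))
                    emit(phase, "retention_error_pct", animal_id, window.day_index,
                         retention_error_pct(store, animal_id, corner, window))
                else:  # place preference / reversal
                    emit(phase, "total_visits", animal_id, window.day_index, float(nv))
                    emit(phase, "total_licks", animal_id, window.day_index,
                         float(total_licks(store, animal_id, window)))
                    emit(phase, "pct_correct", animal_id, window.day_index,
                         pct_correct_place(store, animal_id, window, corner))
                    emit(phase, "correct_visit_with_lick", animal_id, window.day_index,
                         correct_visit_with_lick(store, animal_id, window, corner))

    return pd.DataFrame(
        rows, columns=["phase", "metric", "animal_id", "genotype", "day", "value"]
    )


def write_metric_tables(metrics_df: pd.DataFrame, out_dir) -> None:
    """``metrics.tsv`` plus one ``<phase>_day<k>.tsv`` per phase-day."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_df.to_csv(out_dir / "metrics.tsv", sep="\t", index=False, lineterminator="\n")
    for (phase, day), sub in metrics_df.groupby(["phase", "day"]):
        wide = sub.pivot_table(
            index=["animal_id", "genotype"], columns="metric", values="value",
            aggfunc="first", dropna=False,
        ).reset_index()
        wide.to_csv(out_dir / f"{phase}_day{int(day)}.tsv", sep="\t",
                    index=False, lineterminator="\n")
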