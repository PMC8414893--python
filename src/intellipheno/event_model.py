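"""Event-log data model for automated home-cage (IntelliCage-style) experiments.

The apparatus registers three kinds of time-stamped events per RFID-tagged
animal: corner *visits* (whole-body entries bounded by entry/exit times),
*nosepokes* at a corner's nose ports, and *licks* at the waterspout.  An
:class:`EventStore` bundles the animal roster, the three event tables, the
phase schedule and the per-phase reward-corner assignments into a single
validated relational object, interchanged on disk as a directory of
tab-separated text files.

Time is expressed in seconds since a session epoch recorded in the schedule;
analysis windows are half-open 24-h slices anchored at each phase's start
(phases begin when the controller program switches, not at midnight).  A
visit — and every nosepoke and lick inside it — is attributed to the day
window containing its entry time, so per-day counts sum exactly to
whole-phase counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400
#: lights on 06:00-20:00, as offsets (s) within each 24-h day from the epoch
LIGHTS_ON_OFFSET = 6 * 3600
LIGHTS_OFF_OFFSET = 20 * 3600

CORNERS = (1, 2, 3, 4)
GENOTYPES = ("NonTg", "TG")
SIDES = ("left", "right")


class Phase(str, enum.Enum):
    """The nine consecutive stages of the 29-day testing battery."""

    FREE_ADAPT = "free_adapt"
    DOOR_ADAPT = "door_adapt"
    NOSEPOKE_ADAPT = "nosepoke_adapt"
    PLACE_PREF = "place_pref"
    REVERSAL = "reversal"
    SRT = "srt"
    AVOIDANCE = "avoidance"
    DELAY_OFFCAGE = "delay_offcage"
    RETENTION = "retention"


#: default durations (days) of each phase, in battery order; total 29 days
DEFAULT_DURATIONS: dict[Phase, int] = {
    Phase.FREE_ADAPT: 3,
    Phase.DOOR_ADAPT: 3,
    Phase.NOSEPOKE_ADAPT: 3,
    Phase.PLACE_PREF: 6,
    Phase.REVERSAL: 6,
    Phase.SRT: 3,
    Phase.AVOIDANCE: 1,
    Phase.DELAY_OFFCAGE: 1,
    Phase.RETENTION: 3,
}

ADAPTATION_PHASES = (Phase.FREE_ADAPT, Phase.DOOR_ADAPT, Phase.NOSEPOKE_ADAPT)


class ValidationError(ValueError):
    """An event store violates a structural invariant."""


@dataclass(frozen=True)
class PhaseSpan:
    """One scheduled phase: name, start time (s since epoch), whole days."""

    phase: Phase
    t_start: float
    duration_days: int

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration_days * SECONDS_PER_DAY


@dataclass(frozen=True)
class DayWindow:
    """Half-open 24-h interval ``[t0, t1)``, day_index 1-based within phase."""

    phase: Phase
    day_index: int
    t0: float
    t1: float

    def contains(self, t: float) -> bool:
        return self.t0 <= t < self.t1


def default_schedule(t_start: float = 0.0) -> list[PhaseSpan]:
    """The standard 29-day battery starting at ``t_start`` seconds."""
    spans = []
    t = float(t_start)
    for phase, days in DEFAULT_DURATIONS.items():
        spans.append(PhaseSpan(phase, t, days))
        t += days * SECONDS_PER_DAY
    return spans


_ANIMAL_COLS = ["animal_id", "genotype", "cage_id"]
_VISIT_COLS = ["visit_id", "animal_id", "corner", "t_start", "t_end"]
_POKE_COLS = ["visit_id", "side", "t"]
_LICK_COLS = ["visit_id", "t"]
_ASSIGN_COLS = ["phase", "animal_id", "corner"]


def _empty(cols: list[str], dtypes: dict[str, type]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=dtypes.get(c, float)) for c in cols})


def empty_frames() -> dict[str, pd.DataFrame]:
    return {
        "animals": _empty(_ANIMAL_COLS, {"animal_id": str, "genotype": str, "cage_id": np.int64}),
        "visits": _empty(_VISIT_COLS, {"visit_id": np.int64, "animal_id": str, "corner": np.int64}),
        "nosepokes": _empty(_POKE_COLS, {"visit_id": np.int64, "side": str}),
        "licks": _empty(_LICK_COLS, {"visit_id": np.int64}),
        "assignments": _empty(_ASSIGN_COLS, {"phase": str, "animal_id": str, "corner": np.int64}),
    }


@dataclass(eq=False)
class EventStore:
    """Validated relational collection of animals, events, and the schedule.

    All cross-references must resolve (every nosepoke/lick to an existing
    visit, every visit to an existing animal) and every event must fall
    inside the scheduled session span.  The store is treated as immutable
    after construction; derived per-animal feature caches key off that.
    """

    animals: pd.DataFrame
    visits: pd.DataFrame
    nosepokes: pd.DataFrame
    licks: pd.DataFrame
    schedule: list[PhaseSpan]
    assignments: pd.DataFrame = None  # type: ignore[assignment]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.assignments is None:
            self.assignments = empty_frames()["assignments"]

    # -- schedule helpers -------------------------------------------------
    def phase_span(self, phase: Phase | str) -> PhaseSpan:
        phase = Phase(phase)
        for span in self.schedule:
            if span.phase == phase:
                return span
        raise KeyError(f"phase {phase.value!r} not in schedule")

    @property
    def session_start(self) -> float:
        return min(s.t_start for s in self.schedule)

    @property
    def session_end(self) -> float:
        return max(s.t_end for s in self.schedule)

    def corner_assignment(self, phase: Phase | str) -> dict[str, int]:
        phase = Phase(phase)
        sub = self.assignments[self.assignments["phase"] == phase.value]
        return dict(zip(sub["animal_id"], sub["corner"].astype(int)))

    # -- equality / copy --------------------------------------------------
    def equals(self, other: "EventStore") -> bool:
        """Field-by-field equality (frames compared on sorted canonical order)."""
        if self.schedule != other.schedule:
            return False
        for name in ("animals", "visits", "nosepokes", "licks", "assignments"):
            a = _canonical(name, getattr(self, name))
            b = _canonical(name, getattr(other, name))
            if not a.equals(b):
                return False
        return True

    def copy(self) -> "EventStore":
        return EventStore(
            animals=self.animals.copy(),
            visits=self.visits.copy(),
            nosepokes=self.nosepokes.copy(),
            licks=self.licks.copy(),
            schedule=list(self.schedule),
            assignments=self.assignments.copy(),
        )

    def validate(self) -> "EventStore":
        validate_store(self)
        return self


def _canonical(name: str, df: pd.DataFrame) -> pd.DataFrame:
    sort_keys = {
        "animals": ["animal_id"],
        "visits": ["t_start", "visit_id"],
        "nosepokes": ["t", "visit_id", "side"],
        "licks": ["t", "visit_id"],
        "assignments": ["phase", "animal_id"],
    }[name]
    return df.sort_values(sort_keys, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_store(store: EventStore) -> None:
    """Check every structural invariant; raise :class:`ValidationError`
    naming the first offending row."""
    animals, visits = store.animals, store.visits

    if animals["animal_id"].duplicated().any():
        dup = animals.loc[animals["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ValidationError(f"duplicate animal_id {dup!r}")
    bad_gt = ~animals["genotype"].isin(GENOTYPES)
    if bad_gt.any():
        row = animals[bad_gt].iloc[0]
        raise ValidationError(f"animal {row['animal_id']!r}: unknown genotype {row['genotype']!r}")

    if not store.schedule:
        raise ValidationError("empty phase schedule")
    spans = sorted(store.schedule, key=lambda s: s.t_start)
    for a, b in zip(spans, spans[1:]):
        if not np.isclose(a.t_end, b.t_start):
            raise ValidationError(
                f"schedule not contiguous: {a.phase.value} ends at {a.t_end}, "
                f"{b.phase.value} starts at {b.t_start}"
            )
    t_lo, t_hi = spans[0].t_start, spans[-1].t_end

    if visits["visit_id"].duplicated().any():
        dup = visits.loc[visits["visit_id"].duplicated(), "visit_id"].iloc[0]
        raise ValidationError(f"duplicate visit_id {dup}")
    known = set(animals["animal_id"])
    bad = ~visits["animal_id"].isin(known)
    if bad.any():
        row = visits[bad].iloc[0]
        raise ValidationError(f"visit {row['visit_id']}: unknown animal {row['animal_id']!r}")
    bad = ~visits["corner"].isin(CORNERS)
    if bad.any():
        row = visits[bad].iloc[0]
        raise ValidationError(f"visit {row['visit_id']}: corner {row['corner']} outside 1-4")
    bad = ~(visits["t_start"] < visits["t_end"])
    if bad.any():
        row = visits[bad].iloc[0]
        raise ValidationError(f"visit {row['visit_id']}: t_start >= t_end")
    bad = (visits["t_start"] < t_lo) | (visits["t_end"] > t_hi)
    if bad.any():
        row = visits[bad].iloc[0]
        raise ValidationError(f"visit {row['visit_id']}: outside scheduled session span")

    # per-animal visits must be pairwise non-overlapping
    v = visits.sort_values(["animal_id", "t_start"])
    same = v["animal_id"].values[1:] == v["animal_id"].values[:-1]
    overlap = same & (v["t_start"].values[1:] < v["t_end"].values[:-1])
    if overlap.any():
        i = int(np.flatnonzero(overlap)[0]) + 1
        raise ValidationError(
            f"visit {v['visit_id'].iloc[i]}: overlaps previous visit of animal "
            f"{v['animal_id'].iloc[i]!r}"
        )

    vidx = visits.set_index("visit_id")
    for name, events in (("nosepoke", store.nosepokes), ("lick", store.licks)):
        if len(events) == 0:
            continue
        bad = ~events["visit_id"].isin(vidx.index)
        if bad.any():
            row = events[bad].iloc[0]
            raise ValidationError(f"{name}: unknown visit_id {row['visit_id']}")
        vs = vidx.loc[events["visit_id"], "t_start"].values
        ve = vidx.loc[events["visit_id"], "t_end"].values
        t = events["t"].values
        bad = (t < vs) | (t > ve)
        if bad.any():
            row = events[np.asarray(bad)].iloc[0]
            raise ValidationError(
                f"{name} at t={row['t']}: outside interval of visit {row['visit_id']}"
            )
    if len(store.nosepokes) and not store.nosepokes["side"].isin(SIDES).all():
        bad = store.nosepokes[~store.nosepokes["side"].isin(SIDES)].iloc[0]
        raise ValidationError(f"nosepoke: unknown side {bad['side']!r}")

    if len(store.assignments):
        bad = ~store.assignments["animal_id"].isin(known)
        if bad.any():
            row = store.assignments[bad].iloc[0]
            raise ValidationError(f"assignment: unknown animal {row['animal_id']!r}")
        if not store.assignments["corner"].isin(CORNERS).all():
            raise ValidationError("assignment: corner outside 1-4")


# ---------------------------------------------------------------------------
# on-disk dialect: UTF-8 TSV, '.' decimal, header row
# ---------------------------------------------------------------------------

_FILES = {
    "animals": ("animals.tsv", _ANIMAL_COLS),
    "visits": ("visits.tsv", _VISIT_COLS),
    "nosepokes": ("nosepokes.tsv", _POKE_COLS),
    "licks": ("licks.tsv", _LICK_COLS),
    "assignments": ("assignments.tsv", _ASSIGN_COLS),
}
_SCHEDULE_FILE = "schedule.tsv"


def write_store(store: EventStore, directory: str | Path) -> None:
    """Write a store as tab-separated files; deterministic and sorted, so
    repeated calls are byte-identical."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, (fname, cols) in _FILES.items():
        df = _canonical(name, getattr(store, name))[cols]
        df.to_csv(directory / fname, sep="\t", index=False, lineterminator="\n",
                  float_format="%.17g")
    sched = pd.DataFrame(
        {
            "phase": [s.phase.value for s in store.schedule],
            "t_start": [s.t_start for s in store.schedule],
            "duration_days": [s.duration_days for s in store.schedule],
        }
    ).sort_values("t_start", kind="mergesort")
    sched.to_csv(directory / _SCHEDULE_FILE, sep="\t", index=False, lineterminator="\n",
                 float_format="%.17g")


def read_store(directory: str | Path, validate: bool = True) -> EventStore:
    """Read a store directory written by :func:`write_store`.

    Raises ``FileNotFoundError`` naming any missing required file and
    :class:`ValidationError` on any invariant violation.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, (fname, cols) in _FILES.items():
        path = directory / fname
        if not path.exists():
            if name == "assignments":
                frames[name] = empty_frames()["assignments"]
                continue
            raise FileNotFoundError(f"missing required file: {path}")
        dtypes = {"animal_id": str, "genotype": str, "side": str, "phase": str}
        df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                         dtype={c: dtypes[c] for c in cols if c in dtypes})
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"{fname}: missing columns {missing}")
        frames[name] = df[cols]
    spath = directory / _SCHEDULE_FILE
    if not spath.exists():
        raise FileNotFoundError(f"missing required file: {spath}")
    sched_df = pd.read_csv(spath, sep="\t", float_precision="round_trip")
    schedule = [
        PhaseSpan(Phase(r.phase), float(r.t_start), int(r.duration_days))
        for r in sched_df.itertuples()
    ]
    for name in frames:
        casts: dict[str, type] = {}
        for c in frames[name].columns:
            if c in ("t", "t_start", "t_end"):
                casts[c] = float
            elif c in ("visit_id", "corner", "cage_id"):
                casts[c] = np.int64
        frames[name] = frames[name].astype(casts)
    store = EventStore(schedule=schedule, **frames)
    if validate:
        validate_store(store)
    return store


# ---------------------------------------------------------------------------
# 24-h slicing and per-window event selection
# ---------------------------------------------------------------------------

def slice_days(store: EventStore, phase: Phase | str) -> list[DayWindow]:
    """One half-open 24-h window per scheduled day of ``phase``,
    anchored at the phase's start time."""
    span = store.phase_span(phase)
    return [
        DayWindow(span.phase, k, span.t_start + (k - 1) * SECONDS_PER_DAY,
                  span.t_start + k * SECONDS_PER_DAY)
        for k in range(1, span.duration_days + 1)
    ]


def _per_animal_features(store: EventStore) -> dict[str, dict[str, np.ndarray]]:
    """Per-animal visit feature arrays (entry time, corner, poke/lick
    presence and counts), cached on the store. Assumes immutability."""
    cached = store._cache.get("features")
    if cached is not None:
        return cached
    visits = store.visits
    n_pokes = store.nosepokes.groupby("visit_id").size()
    n_licks = store.licks.groupby("visit_id").size()
    feat = visits[["visit_id", "animal_id", "corner", "t_start", "t_end"]].copy()
    feat["n_pokes"] = feat["visit_id"].map(n_pokes).fillna(0).astype(int)
    feat["n_licks"] = feat["visit_id"].map(n_licks).fillna(0).astype(int)
    feat = feat.sort_values(["animal_id", "t_start"], kind="mergesort")
    out: dict[str, dict[str, np.ndarray]] = {}
    for animal_id, sub in feat.groupby("animal_id", sort=False):
        out[str(animal_id)] = {
            "visit_id": sub["visit_id"].to_numpy(),
            "corner": sub["corner"].to_numpy(),
            "t_start": sub["t_start"].to_numpy(float),
            "t_end": sub["t_end"].to_numpy(float),
            "n_pokes": sub["n_pokes"].to_numpy(),
            "n_licks": sub["n_licks"].to_numpy(),
        }
    for animal_id in store.animals["animal_id"]:
        out.setdefault(str(animal_id), {k: np.array([]) for k in
                       ("visit_id", "corner", "t_start", "t_end", "n_pokes", "n_licks")})
    store._cache["features"] = out
    return out


def animal_window_visits(store: EventStore, animal_id: str, window: DayWindow) -> dict[str, np.ndarray]:
    """Feature arrays of the visits attributed to ``window`` (entry-time rule)."""
    feats = _per_animal_features(store)
    if animal_id not in feats:
        raise KeyError(f"unknown animal {animal_id!r}")
    f = feats[animal_id]
    lo, hi = np.searchsorted(f["t_start"], [window.t0, window.t1])
    return {k: v[lo:hi] for k, v in f.items()}


def events_in(
    store: EventStore, animal_id: str, window: DayWindow
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Time-sorted (visits, nosepokes, licks) attributed to ``window``.

    A visit belongs to the window iff its entry time lies in it; its
    nosepokes and licks follow the visit regardless of their own timestamps,
    so per-day counts conserve whole-phase totals.
    """
    if animal_id not in set(store.animals["animal_id"]):
        raise KeyError(f"unknown animal {animal_id!r}")
    mask = (
        (store.visits["animal_id"] == animal_id)
        & (store.visits["t_start"] >= window.t0)
        & (store.visits["t_start"] < window.t1)
    )
    visits = store.visits[mask].sort_values("t_start", kind="mergesort").reset_index(drop=True)
    vids = set(visits["visit_id"])
    pokes = (
        store.nosepokes[store.nosepokes["visit_id"].isin(vids)]
        .sort_values("t", kind="mergesort")
        .reset_index(drop=True)
    )
    licks = (
        store.licks[store.licks["visit_id"].isin(vids)]
        .sort_values("t", kind="mergesort")
        .reset_index(drop=True)
    )
    return visits, pokes, licks
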