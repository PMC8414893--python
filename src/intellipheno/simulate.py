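"""Stochastic mouse-agent simulator producing synthetic home-cage event logs.

Each agent emits corner visits from a two-level (dark/light) Poisson process
with a decaying novelty boost after introduction, chooses corners by
normalized preference weights reinforced after every rewarded drink
(``w_c <- w_c + alpha * (1 - w_c)``, then renormalized), and interacts with
the phase controllers of :mod:`intellipheno.protocols`: doors decide whether
a drinking bout happens, the SRT machine classifies its trials, and airpuffs
multiplicatively suppress the punished corner's weight.  A configurable
fraction of animals never learns to drink (zero licks) and is subject to the
24-h removal rule, truncating their event streams exactly as the live
protocol would.

The generator is fully deterministic given its seed (one generator stream,
animals simulated in roster order, events merged by time afterwards), and
every store it produces passes :func:`intellipheno.event_model.validate_store`.
Ground-truth parameters are returned alongside the store for recovery tests.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import protocols
from .event_model import (
    DEFAULT_DURATIONS,
    LIGHTS_OFF_OFFSET,
    LIGHTS_ON_OFFSET,
    SECONDS_PER_DAY,
    EventStore,
    Phase,
    PhaseSpan,
    default_schedule,
    empty_frames,
    validate_store,
)

REMOVAL_HOURS = 7  # time in a standard cage after a zero-lick day
MAX_ANIMALS_PER_CAGE = 16


@dataclass(frozen=True)
class MouseParams:
    """Behavioral parameters of one genotype's agents."""

    visit_rate_dark: float   # visits/hour, lights off
    visit_rate_light: float  # visits/hour, lights on
    w_explore: float         # P(visit is exploratory rather than water-seeking)
    learning_rate: float     # alpha of the preference reinforcement
    p_drink_fail: float      # P(animal never learns to drink -> zero licks)
    licks_per_bout_mean: float
    p_attend: float          # P(respond during the 7 s SRT cue window)
    p_impulsive: float       # P(premature poke per SRT trial)
    rt_scale: float          # seconds; latency scale of cue responses
    avoid_learn: float       # beta: per-airpuff suppression of return probability

    def __post_init__(self) -> None:
        for name in ("w_explore", "p_drink_fail", "p_attend", "p_impulsive",
                     "avoid_learn", "learning_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("visit_rate_dark", "visit_rate_light", "rt_scale",
                     "licks_per_bout_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class BehaviorConstants:
    """Genotype-independent calibration constants."""

    novelty_boost: float = 0.8
    explore_poke_prob: float = 0.5
    explore_drink_prob: float = 0.2
    extinction_rate: float = 0.10
    visit_duration_median_s: float = 20.0
    visit_duration_sigma: float = 0.8
    lick_interval_s: float = 0.15


@dataclass
class SimConfig:
    """Cohort design: group sizes per cage, per-genotype parameters, schedule, seed."""

    n_nontg_per_cage: int
    n_tg_per_cage: int
    n_cages: int
    seed: int
    params: dict[str, MouseParams]
    behavior: BehaviorConstants = field(default_factory=BehaviorConstants)
    schedule: list[PhaseSpan] = field(default_factory=default_schedule)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_nontg_per_cage + self.n_tg_per_cage > MAX_ANIMALS_PER_CAGE:
            raise ValueError(
                f"{self.n_nontg_per_cage + self.n_tg_per_cage} animals per cage "
                f"exceed the {MAX_ANIMALS_PER_CAGE}-animal capacity"
            )
        if self.n_cages < 1 or self.n_nontg_per_cage < 0 or self.n_tg_per_cage < 0:
            raise ValueError("invalid cohort sizes")
        for g in ("NonTg", "TG"):
            if g not in self.params:
                raise ValueError(f"missing parameters for genotype {g!r}")


def load_config(path: str | Path | None = None) -> SimConfig:
    """Load the packaged default configuration, optionally overridden by a
    user TOML file with the same table layout."""
    with resources.files("intellipheno").joinpath("default_config.toml").open("rb") as fh:
        raw = tomllib.load(fh)
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for table, values in user.items():
            if isinstance(values, dict):
                for k, v in values.items():
                    if isinstance(v, dict):
                        raw.setdefault(table, {}).setdefault(k, {}).update(v)
                    else:
                        raw.setdefault(table, {})[k] = v
            else:
                raw[table] = values
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimConfig:
    cohort = raw["cohort"]
    sched_cfg = raw.get("schedule", {})
    t0 = float(sched_cfg.get("t_start", 0.0))
    spans = []
    t = t0
    for phase, default_days in DEFAULT_DURATIONS.items():
        days = int(sched_cfg.get(phase.value, default_days))
        spans.append(PhaseSpan(phase, t, days))
        t += days * SECONDS_PER_DAY
    params = {g: MouseParams(**raw["params"][g]) for g in ("NonTg", "TG")}
    behavior = BehaviorConstants(**raw.get("behavior", {}))
    return SimConfig(
        n_nontg_per_cage=int(cohort["n_nontg_per_cage"]),
        n_tg_per_cage=int(cohort["n_tg_per_cage"]),
        n_cages=int(cohort["n_cages"]),
        seed=int(cohort["seed"]),
        params=params,
        behavior=behavior,
        schedule=spans,
    )


def default_config(seed: int = 0, **overrides) -> SimConfig:
    cfg = load_config()
    cfg.seed = seed
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def write_ground_truth(config: SimConfig, path: str | Path) -> None:
    """Serialize the configuration actually used (TOML)."""
    lines = ["[cohort]"]
    for k in ("n_nontg_per_cage", "n_tg_per_cage", "n_cages", "seed"):
        lines.append(f"{k} = {getattr(config, k)}")
    lines.append("\n[schedule]")
    lines.append(f"t_start = {config.schedule[0].t_start}")
    for span in config.schedule:
        lines.append(f"{span.phase.value} = {span.duration_days}")
    for g, p in config.params.items():
        lines.append(f"\n[params.{g}]")
        for k, v in asdict(p).items():
            lines.append(f"{k} = {v}")
    lines.append("\n[behavior]")
    for k, v in asdict(config.behavior).items():
        lines.append(f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# the agent
# ---------------------------------------------------------------------------

def _truncated_exp(rng: np.random.Generator, scale: float, upper: float) -> float:
    u = rng.random()
    return -scale * math.log1p(-u * (1.0 - math.exp(-upper / scale)))


class _Agent:
    """State of one simulated mouse: corner preferences and event buffers."""

    def __init__(self, animal_id: str, genotype: str, cage_id: int,
                 params: MouseParams, behavior: BehaviorConstants,
                 drinker: bool) -> None:
        self.animal_id = animal_id
        self.genotype = genotype
        self.cage_id = cage_id
        self.p = params
        self.b = behavior
        self.drinker = drinker
        self.w = np.full(4, 0.25)
        self.t_cursor = 0.0
        # absence intervals (start, end); exclusion uses end = +inf
        self.absences: list[tuple[float, float]] = []
        # event buffers: visits as [corner, t_start, t_end]; pokes and lick
        # bouts reference the local visit index
        self.visits: list[tuple[int, float, float]] = []
        self.pokes: list[tuple[int, float]] = []
        self.lick_bouts: list[tuple[int, float, int]] = []  # (visit idx, t0, n)

    # -- preference dynamics ---------------------------------------------
    def reinforce(self, corner: int) -> None:
        i = corner - 1
        self.w[i] += self.p.learning_rate * (1.0 - self.w[i])
        self.w /= self.w.sum()

    def _decay(self, corner: int, factor: float) -> None:
        self.w[corner - 1] *= factor
        s = self.w.sum()
        if s <= 0:  # total weight collapse; re-spread uniformly
            self.w = np.full(4, 0.25)
        else:
            self.w /= s

    def suppress(self, corner: int) -> None:
        """Airpuff punishment: return probability scaled by (1 - beta)."""
        self._decay(corner, 1.0 - self.p.avoid_learn)

    def extinguish(self, corner: int) -> None:
        """Operant extinction: a poke that yields no water weakens the
        corner-reward association."""
        self._decay(corner, 1.0 - self.b.extinction_rate)

    def choose_corner(self, rng: np.random.Generator) -> tuple[int, bool]:
        explore = rng.random() < self.p.w_explore
        if explore:
            return int(rng.integers(1, 5)), True
        return int(np.argmax(self.w)) + 1, False

    def absent_at(self, t: float) -> float | None:
        """End of the absence interval containing ``t``, if any."""
        for a, b in self.absences:
            if a <= t < b:
                return b
        return None


def _simulate_span(
    agent: _Agent,
    rng: np.random.Generator,
    schedule: list[PhaseSpan],
    span_start: float,
    span_end: float,
    assignment: dict[Phase, int],
) -> None:
    """Emit events for ``agent`` over ``[span_start, span_end)``."""
    p, b = agent.p, agent.b
    session_t0 = schedule[0].t_start
    rate_max = max(p.visit_rate_dark, p.visit_rate_light) * (1.0 + b.novelty_boost) / 3600.0
    ln_med = math.log(b.visit_duration_median_s)

    spans = sorted(schedule, key=lambda s: s.t_start)

    def phase_at(t: float) -> Phase | None:
        for s in spans:
            if s.t_start <= t < s.t_end:
                return s.phase
        return None

    def rate(t: float) -> float:
        tod = (t - session_t0) % SECONDS_PER_DAY
        base = p.visit_rate_light if LIGHTS_ON_OFFSET <= tod < LIGHTS_OFF_OFFSET else p.visit_rate_dark
        base *= 1.0 + b.novelty_boost * math.exp(-(t - session_t0) / SECONDS_PER_DAY)
        return base / 3600.0

    t = max(agent.t_cursor, span_start)
    while True:
        t += rng.exponential(1.0 / rate_max)
        if t >= span_end:
            break
        resume = agent.absent_at(t)
        if resume is not None:
            if math.isinf(resume):
                break
            t = resume
            continue
        if rng.random() >= rate(t) / rate_max:
            continue
        phase = phase_at(t)
        if phase is None or phase is Phase.DELAY_OFFCAGE:
            continue
        _do_visit(agent, rng, phase, t, assignment, ln_med, span_end)
        t = agent.visits[-1][2]  # next visit cannot start before this one ends
    last_end = agent.visits[-1][2] if agent.visits else span_end
    agent.t_cursor = max(agent.t_cursor, span_end, last_end)


def _do_visit(
    agent: _Agent,
    rng: np.random.Generator,
    phase: Phase,
    t: float,
    assignment: dict[Phase, int],
    ln_med: float,
    hard_end: float,
) -> None:
    p, b = agent.p, agent.b
    corner, explore = agent.choose_corner(rng)
    dur = rng.lognormal(ln_med, b.visit_duration_sigma)
    t_end = t + min(dur, 1800.0)

    vi = len(agent.visits)
    poke_times: list[float] = []
    wants_drink = (not explore) or rng.random() < b.explore_drink_prob
    will_poke = (not explore) or rng.random() < b.explore_poke_prob
    drink_t: float | None = None
    assigned = assignment.get(phase)

    if phase in (Phase.FREE_ADAPT, Phase.DOOR_ADAPT):
        # door open (free) or opens on entry (door adaptation)
        if explore and will_poke:
            poke_times.append(t + rng.uniform(0.3, 3.0))
        if wants_drink and agent.drinker:
            drink_t = t + rng.uniform(0.5, 2.0)
    elif phase in (Phase.NOSEPOKE_ADAPT, Phase.RETENTION):
        if will_poke:
            tp = t + rng.uniform(0.3, 3.0)
            poke_times.append(tp)
            if wants_drink and agent.drinker:
                drink_t = tp + 0.5
    elif phase in (Phase.PLACE_PREF, Phase.REVERSAL):
        if will_poke:
            tp = t + rng.uniform(0.3, 3.0)
            poke_times.append(tp)
            if corner == assigned:
                if wants_drink and agent.drinker:
                    drink_t = tp + 0.5
            else:
                agent.extinguish(corner)  # poked, door stays closed
    elif phase is Phase.SRT:
        if corner == assigned and will_poke:
            t_init = t + rng.uniform(0.3, 1.5)
            poke_times.append(t_init)
            if rng.random() < p.p_impulsive:
                poke_times.append(t_init + rng.uniform(0.05, 1.95))
            elif rng.random() < p.p_attend:
                lat = _truncated_exp(rng, p.rt_scale, protocols.CUE_DURATION_S)
                tr = t_init + protocols.PRECUE_DELAY_S + min(lat, protocols.CUE_DURATION_S)
                poke_times.append(tr)
                if agent.drinker and wants_drink:
                    drink_t = tr + 0.5
            else:
                # cue times out: the animal lingers past the 9 s trial span
                t_end = max(t_end, t_init + protocols.TRIAL_SPAN_S + 0.5)
        elif will_poke:
            poke_times.append(t + rng.uniform(0.3, 3.0))
            agent.extinguish(corner)  # wrong corner: door never opens
    elif phase is Phase.AVOIDANCE:
        if will_poke:
            tp = t + rng.uniform(0.3, 3.0)
            poke_times.append(tp)
            agent.extinguish(corner)  # no water anywhere in this phase
            if assigned is not None and protocols.airpuff_triggered(
                {agent.animal_id: assigned}, agent.animal_id, corner, True
            ):
                agent.suppress(corner)

    n_licks = 0
    if drink_t is not None:
        n_licks = 1 + int(rng.poisson(max(p.licks_per_bout_mean - 1.0, 0.0)))
        t_last_lick = drink_t + (n_licks - 1) * b.lick_interval_s
        t_end = max(t_end, t_last_lick + 0.5)

    if poke_times:
        t_end = max(t_end, poke_times[-1] + 0.5)
    # keep the visit inside the current stage; drop trailing events if clipped
    if t_end > hard_end:
        t_end = hard_end
        poke_times = [x for x in poke_times if x < t_end]
        if drink_t is not None and drink_t + (n_licks - 1) * b.lick_interval_s >= t_end:
            n_licks = max(0, int((t_end - drink_t) / b.lick_interval_s))
            if n_licks == 0:
                drink_t = None
    if drink_t is not None and n_licks > 0:
        agent.reinforce(corner)

    agent.visits.append((corner, t, t_end))
    for tp in poke_times:
        agent.pokes.append((vi, tp))
    if drink_t is not None and n_licks > 0:
        agent.lick_bouts.append((vi, drink_t, n_licks))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> tuple[EventStore, SimConfig]:
    """Simulate a full cohort; returns the validated store and the
    ground-truth configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    schedule = sorted(config.schedule, key=lambda s: s.t_start)
    adapt_end = max(
        s.t_end for s in schedule
        if s.phase in (Phase.FREE_ADAPT, Phase.DOOR_ADAPT, Phase.NOSEPOKE_ADAPT)
    )
    session_end = schedule[-1].t_end
    t0 = schedule[0].t_start
    day = SECONDS_PER_DAY

    agents: list[_Agent] = []
    for cage in range(1, config.n_cages + 1):
        for g, prefix, n in (
            ("NonTg", "N", config.n_nontg_per_cage),
            ("TG", "T", config.n_tg_per_cage),
        ):
            for j in range(1, n + 1):
                aid = f"C{cage}{prefix}{j:02d}"
                drinker = rng.random() >= config.params[g].p_drink_fail
                agents.append(
                    _Agent(aid, g, cage, config.params[g], config.behavior, drinker)
                )

    # non-drinkers follow the live removal rule: zero licks on day 1 ->
    # 7 h out of the cage; zero licks again after reintroduction -> excluded
    for a in agents:
        if not a.drinker:
            a.absences.append((t0 + day, t0 + day + REMOVAL_HOURS * 3600))
            a.absences.append((t0 + 2 * day, math.inf))

    # stage 1: adaptation phases (no per-animal corner assignment yet)
    for a in agents:
        _simulate_span(a, rng, schedule, t0, adapt_end, {})

    # reward corners from adaptation visit habits, balanced per cage
    assign_rows: list[tuple[str, str, int]] = []
    per_animal_assignment: dict[str, dict[Phase, int]] = {a.animal_id: {} for a in agents}
    for cage in sorted({a.cage_id for a in agents}):
        survivors = [a for a in agents if a.cage_id == cage and a.drinker]
        if not survivors:
            continue
        counts = {}
        for a in survivors:
            c = np.zeros(4, dtype=int)
            for corner, ts, _ in a.visits:
                c[corner - 1] += 1
            counts[a.animal_id] = c.tolist()
        genos = {a.animal_id: a.genotype for a in survivors}
        assignment = None
        for imbalance in range(1, len(survivors) + 1):
            try:
                assignment = protocols.assign_corners(
                    counts, genos, max_per_corner=4, max_imbalance=imbalance
                )
                break
            except protocols.AssignmentError:
                continue
        assert assignment is not None
        for aid, corner in assignment.items():
            rev = protocols.reversal_corner(corner)
            per_phase = {
                Phase.PLACE_PREF: corner,
                Phase.REVERSAL: rev,
                Phase.SRT: rev,          # SRT runs in the reversal corner
                Phase.AVOIDANCE: rev,    # airpuff corner = SRT corner
                Phase.RETENTION: rev,    # former airpuff corner, for scoring
            }
            per_animal_assignment[aid] = per_phase
            for ph, c in per_phase.items():
                assign_rows.append((ph.value, aid, c))

    # stage 2: the remaining phases
    for a in agents:
        _simulate_span(a, rng, schedule, adapt_end, session_end,
                       per_animal_assignment[a.animal_id])

    store = _build_store(agents, schedule, assign_rows, rng)
    validate_store(store)
    return store, config


def _build_store(
    agents: list[_Agent],
    schedule: list[PhaseSpan],
    assign_rows: list[tuple[str, str, int]],
    rng: np.random.Generator,
) -> EventStore:
    frames = empty_frames()
    animals = pd.DataFrame(
        {
            "animal_id": [a.animal_id for a in agents],
            "genotype": [a.genotype for a in agents],
            "cage_id": [a.cage_id for a in agents],
        }
    )

    aid_list, corner_l, ts_l, te_l = [], [], [], []
    poke_owner, poke_t = [], []
    lick_owner, lick_t = [], []
    offset = 0
    for a in agents:
        for corner, ts, te in a.visits:
            aid_list.append(a.animal_id)
            corner_l.append(corner)
            ts_l.append(ts)
            te_l.append(te)
        for vi, tp in a.pokes:
            poke_owner.append(offset + vi)
            poke_t.append(tp)
        for vi, tb, n in a.lick_bouts:
            times = tb + np.arange(n) * a.b.lick_interval_s
            lick_owner.extend([offset + vi] * n)
            lick_t.append(times)
        offset += len(a.visits)

    ts_arr = np.asarray(ts_l, dtype=float)
    order = np.lexsort((np.asarray(aid_list, dtype=object), ts_arr))
    final_id = np.empty(len(order), dtype=np.int64)
    final_id[order] = np.arange(1, len(order) + 1)

    visits = pd.DataFrame(
        {
            "visit_id": final_id,
            "animal_id": np.asarray(aid_list, dtype=object),
            "corner": np.asarray(corner_l, dtype=np.int64),
            "t_start": ts_arr,
            "t_end": np.asarray(te_l, dtype=float),
        }
    )
    if poke_owner:
        sides = np.where(rng.random(len(poke_owner)) < 0.5, "left", "right")
        pokes = pd.DataFrame(
            {
                "visit_id": final_id[np.asarray(poke_owner)],
                "side": sides,
                "t": np.asarray(poke_t, dtype=float),
            }
        )
    else:
        pokes = frames["nosepokes"]
    if lick_owner:
        licks = pd.DataFrame(
            {
                "visit_id": final_id[np.asarray(lick_owner)],
                "t": np.concatenate(lick_t) if lick_t else np.array([]),
            }
        )
    else:
        licks = frames["licks"]
    assignments = (
        pd.DataFrame(assign_rows, columns=["phase", "animal_id", "corner"])
        if assign_rows
        else frames["assignments"]
    )
    return EventStore(
        animals=animals,
        visits=visits,
        nosepokes=pokes,
        licks=licks,
        schedule=list(schedule),
        assignments=assignments,
    )


def remove_and_reintroduce(
    store: EventStore,
    animal_id: str,
    t_removal: float,
    excluded: frozenset[str] | set[str] = frozenset(),
) -> EventStore:
    """Drop all of an animal's events starting within the 7-h removal window
    ``[t_removal, t_removal + 7 h)``; returns a new store.

    ``excluded`` lists animals already removed from the experiment, for which
    temporary removal is no longer meaningful (raises ``ValueError``).
    """
    if animal_id in excluded:
        raise ValueError(f"animal {animal_id!r} is already excluded")
    if animal_id not in set(store.animals["animal_id"]):
        raise KeyError(f"unknown animal {animal_id!r}")
    t_hi = t_removal + REMOVAL_HOURS * 3600
    v = store.visits
    drop = (
        (v["animal_id"] == animal_id) & (v["t_start"] >= t_removal) & (v["t_start"] < t_hi)
    )
    dropped_ids = set(v.loc[drop, "visit_id"])
    out = store.copy()
    out.visits = v[~drop].reset_index(drop=True)
    out.nosepokes = store.nosepokes[~store.nosepokes["visit_id"].isin(dropped_ids)].reset_index(drop=True)
    out.licks = store.licks[~store.licks["visit_id"].isin(dropped_ids)].reset_index(drop=True)
    return out
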