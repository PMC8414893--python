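"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as straight-line loops over raw
event rows / raw matrices, sharing no code path with the package.
"""

from __future__ import annotations

import math
from collections import defaultdict

SECONDS_PER_DAY = 86_400
ADAPT_PHASES = ("free_adapt", "door_adapt", "nosepoke_adapt")

PRECUE = 2.0
CUE = 7.0


# ---------------------------------------------------------------------------
# SRT brute-force classifier
# ---------------------------------------------------------------------------

def brute_force_srt(poke_times):
    """Classify the trial of one assigned-corner visit directly from the
    protocol's wording.  Returns (outcome, reaction_time | None) or None if
    no poke occurred (no trial)."""
    ts = sorted(poke_times)
    if not ts:
        return None
    t1 = ts[0]
    for t in ts[1:]:
        if t < t1 + PRECUE:
            return ("premature", None)
        if t <= t1 + PRECUE + CUE:
            return ("correct", t - (t1 + PRECUE))
        break
    return ("incorrect", None)


# ---------------------------------------------------------------------------
# corner-assignment constraint checker
# ---------------------------------------------------------------------------

def check_assignment(assignment, counts, genotypes, max_per_corner=4, max_imbalance=1):
    """Assert capacity, genotype balance, and membership of every animal."""
    per_corner = defaultdict(lambda: {"NonTg": 0, "TG": 0})
    assert set(assignment) == set(counts)
    for animal, corner in assignment.items():
        assert corner in (1, 2, 3, 4)
        per_corner[corner][genotypes[animal]] += 1
    for corner, c in per_corner.items():
        assert c["NonTg"] + c["TG"] <= max_per_corner, f"corner {corner} over capacity"
        assert abs(c["NonTg"] - c["TG"]) <= max_imbalance, f"corner {corner} imbalanced"


def genotype_split_feasible(n_nontg, n_tg, max_per_corner=4, max_imbalance=1):
    """Brute-force: can the genotype totals be distributed over 4 corners
    within capacity and balance?  Enumerates all per-corner count pairs."""
    import itertools

    types = [
        (a, b)
        for a in range(max_per_corner + 1)
        for b in range(max_per_corner + 1)
        if a + b <= max_per_corner and abs(a - b) <= max_imbalance
    ]
    return any(
        sum(t[0] for t in combo) == n_nontg and sum(t[1] for t in combo) == n_tg
        for combo in itertools.product(types, repeat=4)
    )


# ---------------------------------------------------------------------------
# direct cell-means ANOVA
# ---------------------------------------------------------------------------

def cellmeans_anova(X, groups):
    """Mixed-design F statistics computed from explicit sums over cells."""
    N = len(X)
    d = len(X[0])
    levels = sorted(set(groups))
    g = len(levels)

    grand = sum(X[i][j] for i in range(N) for j in range(d)) / (N * d)
    subj = [sum(X[i]) / d for i in range(N)]
    day = [sum(X[i][j] for i in range(N)) / N for j in range(d)]
    members = {lev: [i for i in range(N) if groups[i] == lev] for lev in levels}
    gmean = {
        lev: sum(X[i][j] for i in members[lev] for j in range(d)) / (len(members[lev]) * d)
        for lev in levels
    }
    cell = {
        (lev, j): sum(X[i][j] for i in members[lev]) / len(members[lev])
        for lev in levels
        for j in range(d)
    }

    ss_group = sum(d * len(members[lev]) * (gmean[lev] - grand) ** 2 for lev in levels)
    ss_subj = sum(
        d * (subj[i] - gmean[lev]) ** 2 for lev in levels for i in members[lev]
    )
    ss_day = sum(N * (day[j] - grand) ** 2 for j in range(d))
    ss_inter = sum(
        len(members[lev]) * (cell[(lev, j)] - gmean[lev] - day[j] + grand) ** 2
        for lev in levels
        for j in range(d)
    )
    ss_err = sum(
        (X[i][j] - cell[(lev, j)] - subj[i] + gmean[lev]) ** 2
        for lev in levels
        for i in members[lev]
        for j in range(d)
    )

    f_between = (ss_group / (g - 1)) / (ss_subj / (N - g))
    f_within = (ss_day / (d - 1)) / (ss_err / ((N - g) * (d - 1)))
    f_inter = (ss_inter / ((g - 1) * (d - 1))) / (ss_err / ((N - g) * (d - 1)))
    return f_between, f_within, f_inter


# ---------------------------------------------------------------------------
# straight-line metric recount over raw event rows
# ---------------------------------------------------------------------------

def recount_metrics(store):
    """Recompute every per-animal per-day metric by plain iteration over the
    raw visit/nosepoke/lick rows.  Returns {(phase, metric, animal, day): value}."""
    spans = {s.phase.value: (s.t_start, s.duration_days) for s in store.schedule}

    visits = {}
    for row in store.visits.itertuples():
        visits[row.visit_id] = {
            "animal": row.animal_id,
            "corner": int(row.corner),
            "ts": float(row.t_start),
            "te": float(row.t_end),
            "pokes": [],
            "licks": 0,
        }
    for row in store.nosepokes.itertuples():
        visits[row.visit_id]["pokes"].append(float(row.t))
    for row in store.licks.itertuples():
        visits[row.visit_id]["licks"] += 1
    for v in visits.values():
        v["pokes"].sort()

    animals = list(store.animals["animal_id"])
    genotype = dict(zip(store.animals["animal_id"], store.animals["genotype"]))
    assignment = defaultdict(dict)
    for row in store.assignments.itertuples():
        assignment[row.phase][row.animal_id] = int(row.corner)

    # bucket visits by (animal, phase, day-of-phase) via the entry-time rule
    buckets = defaultdict(list)
    for v in visits.values():
        for phase, (t0, days) in spans.items():
            if t0 <= v["ts"] < t0 + days * SECONDS_PER_DAY:
                day = int((v["ts"] - t0) // SECONDS_PER_DAY) + 1
                buckets[(v["animal"], phase, day)].append(v)
                break

    # adaptation pass/fail: two consecutive zero-lick 24-h windows
    adapt_days = []
    for phase in ADAPT_PHASES:
        for day in range(1, spans[phase][1] + 1):
            adapt_days.append((phase, day))
    passed = {}
    failure_day = {}
    for a in animals:
        strike = False
        failed_at = None
        for k, (phase, day) in enumerate(adapt_days, start=1):
            licks = sum(v["licks"] for v in buckets[(a, phase, day)])
            if licks == 0:
                if strike:
                    failed_at = k
                    break
                strike = True
            else:
                strike = False
        passed[a] = failed_at is None
        failure_day[a] = failed_at

    out = {}

    def put(phase, metric, animal, day, value):
        out[(phase, metric, animal, day)] = value

    global_day = 0
    for phase in ADAPT_PHASES:
        for day in range(1, spans[phase][1] + 1):
            global_day += 1
            for a in animals:
                if not passed[a] and global_day > failure_day[a]:
                    continue
                vs = buckets[(a, phase, day)]
                put(phase, "total_visits", a, day, float(len(vs)))
                put(phase, "total_licks", a, day, float(sum(v["licks"] for v in vs)))
                if phase == "nosepoke_adapt":
                    put(phase, "visits_with_nosepoke", a, day,
                        float(sum(1 for v in vs if v["pokes"])))
                    if len(vs) == 0:
                        frac = math.nan
                    else:
                        frac = 100.0 * sum(1 for v in vs if v["licks"] > 0) / len(vs)
                    put(phase, "drink_motivated_fraction", a, day, frac)

    for phase in ("place_pref", "reversal"):
        for a in sorted(assignment[phase]):
            if not passed.get(a, True):
                continue
            corner = assignment[phase][a]
            for day in range(1, spans[phase][1] + 1):
                vs = buckets[(a, phase, day)]
                put(phase, "total_visits", a, day, float(len(vs)))
                put(phase, "total_licks", a, day, float(sum(v["licks"] for v in vs)))
                n_corr = sum(1 for v in vs if v["corner"] == corner)
                pc = math.nan if not vs else 100.0 * n_corr / len(vs)
                put(phase, "pct_correct", a, day, pc)
                if n_corr == 0:
                    cvl = math.nan
                else:
                    hits = sum(
                        1 for v in vs
                        if v["corner"] == corner and v["pokes"] and v["licks"] > 0
                    )
                    cvl = 100.0 * hits / n_corr
                put(phase, "correct_visit_with_lick", a, day, cvl)

    for a in sorted(assignment["srt"]):
        if not passed.get(a, True):
            continue
        corner = assignment["srt"][a]
        for day in range(1, spans["srt"][1] + 1):
            vs = buckets[(a, "srt", day)]
            put("srt", "total_visits", a, day, float(len(vs)))
            put("srt", "total_licks", a, day, float(sum(v["licks"] for v in vs)))
            outcomes = []
            rts = []
            for v in vs:
                if v["corner"] != corner:
                    continue
                res = brute_force_srt(v["pokes"])
                if res is None:
                    continue
                outcomes.append(res[0])
                if res[1] is not None:
                    rts.append(res[1])
            n_init = len(outcomes)
            put("srt", "pct_initiated", a, day,
                math.nan if not vs else 100.0 * n_init / len(vs))
            if n_init == 0:
                for m in ("pct_correct", "pct_incorrect", "pct_premature"):
                    put("srt", m, a, day, math.nan)
            else:
                put("srt", "pct_correct", a, day,
                    100.0 * outcomes.count("correct") / n_init)
                put("srt", "pct_incorrect", a, day,
                    100.0 * outcomes.count("incorrect") / n_init)
                put("srt", "pct_premature", a, day,
                    100.0 * outcomes.count("premature") / n_init)
            put("srt", "mean_reaction_time", a, day,
                sum(rts) / len(rts) if rts else math.nan)

    for a in sorted(assignment["avoidance"]):
        if not passed.get(a, True):
            continue
        corner = assignment["avoidance"][a]
        vs = buckets[(a, "avoidance", 1)]
        put("avoidance", "total_visits", a, 1, float(len(vs)))
        put("avoidance", "airpuff_nosepoke_visits", a, 1,
            float(sum(1 for v in vs if v["corner"] == corner and v["pokes"])))

    for a in sorted(assignment["retention"]):
        if not passed.get(a, True):
            continue
        corner = assignment["retention"][a]
        for day in range(1, spans["retention"][1] + 1):
            vs = buckets[(a, "retention", day)]
            put("retention", "total_visits", a, day, float(len(vs)))
            errs = sum(1 for v in vs if v["corner"] == corner and v["pokes"])
            put("retention", "retention_error_pct", a, day,
                math.nan if not vs else 100.0 * errs / len(vs))

    return out


def compare_metric_tables(metrics_df, oracle, tol=1e-9):
    """Assert the package's long-format table matches the oracle dict."""
    got = {
        (r.phase, r.metric, r.animal_id, int(r.day)): r.value
        for r in metrics_df.itertuples()
    }
    assert set(got) == set(oracle), (
        f"key mismatch: {len(set(got) - set(oracle))} extra, "
        f"{len(set(oracle) - set(got))} missing"
    )
    for key, expected in oracle.items():
        actual = got[key]
        if math.isnan(expected):
            assert math.isnan(actual), f"{key}: expected NaN, got {actual}"
        else:
            assert abs(actual - expected) <= tol, f"{key}: {actual} != {expected}"
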