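# intellipheno

Automated home-cage behavioral phenotyping for IntelliCage-style operant
experiments: an event-log data model, the task controllers of a 29-day
testing battery, a stochastic mouse-agent simulator, every per-animal
per-day dependent variable of the battery, and the mixed repeated-measures
statistical analysis — built as a tested, reusable Python package.

## Who this is for

Behavioral neuroscientists analyzing RFID-gated group-housing experiments in
which each of four conditioning corners registers *visits* (whole-body
entries), *nosepokes* (the operant response that opens the waterspout doors)
and *licks* (drinking), with water as the sole motivator.  The package
reconstructs task outcomes from raw event tables, applies the exclusion
rules, computes the behavioral metrics, and runs the statistics — and it
ships a calibrated simulator that generates complete synthetic cohorts with
known ground truth, so every step of the analysis is testable end to end.

## The battery

| Phase | Days | Door rule | Key measures |
|---|---|---|---|
| free adaptation | 3 | always open | total visits, total licks |
| door adaptation | 3 | opens on corner entry | total visits, total licks |
| nosepoke adaptation | 3 | opens on nosepoke | visits with ≥1 nosepoke; % visits with ≥1 lick |
| place preference | 6 | opens on nosepoke in the assigned corner | % correct; correct visits with lick |
| reversal | 6 | same, diagonally opposite corner | % correct; correct visits with lick |
| serial reaction time (SRT) | 3 | opens on a correct trial | % initiated / correct / incorrect / premature; reaction time |
| place avoidance | 1 | all closed; nosepoke in assigned corner → airpuff | visits; airpuff-corner nosepoke visits |
| off-cage delay | 1 | — | — |
| retention | 3 | opens on nosepoke, any corner | % error (former airpuff corner) |

Any animal with a zero-lick 24-h window is removed to a standard cage for
7 h; a second zero-lick window after reintroduction excludes it.

**SRT trial logic.**  The first nosepoke of a visit to the assigned corner
initiates a trial at `t₀`; a green LED lights at `t₀ + 2 s` for 7 s.  A poke
in `(t₀, t₀+2)` is *premature*, a poke in `[t₀+2, t₀+9]` is *correct* with
reaction time `t − (t₀+2)`, and cue timeout is *incorrect*; any outcome
locks the corner until exit, so a visit yields at most one trial, and
%correct + %incorrect + %premature = 100 over initiated trials.

**Statistics.**  For each multi-day metric a mixed (split-plot) ANOVA with
genotype as the between-subjects factor and day as the within-subjects
factor: `F_geno = MS_geno / MS_subj(geno)` on `(g−1, N−g)` df, day and
genotype×day against `MS_error` on `(d−1, (N−g)(d−1))` df.  Sphericity is
assessed with Mauchly's W (chi-square approximation, Greenhouse–Geisser ε
reported); Bonferroni-corrected per-day post hocs run only after a
significant interaction; single-window measures use Student's pooled
two-sample t, computable from raw samples or printed mean ± SEM summaries.

## Worked example

```python
import intellipheno as ip
from intellipheno import metrics as mt, stats as st

store, truth = ip.generate_cohort(ip.default_config(seed=1))   # 8 NonTg + 8 TG
print(mt.pass_summary(store).to_string(index=False))

table = mt.compute_metrics(store)
design = st.RMDesign.from_metric_table(table, "srt", "pct_correct")
res = st.rm_anova(design)
for term in ("between", "within", "interaction"):
    r = res[term]
    print(f"{term:12s} F({r.df1:.0f},{r.df2:.0f}) = {r.statistic:.3f}, p = {r.p:.4f}")
```

prints

```
genotype  n_started  n_passed  pct_passed
   NonTg          8         8       100.0
      TG          8         5        62.5
between      F(1,11) = 24.987, p = 0.0004
within       F(2,22) = 0.063, p = 0.9391
interaction  F(2,22) = 1.560, p = 0.2326
```

Three of the eight simulated TG (transgenic AD-model) animals never learned
to drink and were excluded by the adaptation rule, while every control
passed (62.5% vs 100% for this seed).  Among animals that completed
training, the built-in TG attention deficit (a lower probability of
responding during the SRT cue) surfaces as a strong genotype main effect on
SRT % correct — here 44.9% vs 63.1% across the three task days — with no
day or interaction effect, as the simulated deficit is constant over days.

The same pipeline runs from the shell:

```bash
intellipheno simulate -o run/ --seed 1
intellipheno analyze run/store -o run/out
intellipheno stats run/out/metrics.tsv -o run/out
```

producing a tab-separated event-store directory with ground truth, the
long-format `metrics.tsv` plus per-day tables and the adaptation pass
summary, and `stats_report.tsv` with the full test battery.

## Layout

- `src/intellipheno/event_model.py` — data model, TSV dialect, validation, 24-h slicing
- `src/intellipheno/protocols.py` — door/airpuff rules, SRT state machine, corner assignment
- `src/intellipheno/simulate.py` — mouse-agent cohort generator (`default_config.toml` holds the calibration)
- `src/intellipheno/metrics.py` — all dependent variables and the exclusion rule
- `src/intellipheno/stats.py` — mixed RM-ANOVA, Mauchly, post hocs, t-tests
- `src/intellipheno/cli.py` — `intellipheno simulate|analyze|stats`
- `docs/methods.md` — model assumptions, parameter meanings, numerical choices, limitations
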