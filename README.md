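# msart

A headless, seedable simulator and analysis toolkit for an **adaptive
go/no-go sustained-attention task** (a modified SART) used to quantify
mind-wandering, for researchers who want to exercise the paradigm's scoring
and statistics end-to-end with synthetic participants instead of human data.

In the task, digits 1–9 appear every ~1.5 s; every digit except 3 requires a
keypress ("j"), digit 3 must be withheld. The task holds a difficulty *mode*
m ∈ {1..9} fixing the no-go probability at (1/9, 1/9, 2/9, …, 8/9)[m].
Each no-go commission error escalates the mode; a correct withhold (or a
"b" correction press right after a slip) resets it to mode 1. Because go
responses are automatic, a *run* of commissions — while no-gos become ever
more frequent — marks an attention lapse, and the deepest mode reached
grades it: **mild** (1–3), **moderate** (4–6), **severe** (7–9).

The package provides:

- `msart.engine` — the mode state machine, stimulus scheduler and session
  runner (30-min sessions, 900–1200 ms fixation jitter, 500 ms stimuli,
  18-trial practice block), fully reproducible from a seed;
- `msart.responder` — synthetic participants driven by a two-state Markov
  attention chain (on-task/off-task) with a `severity` knob; off-task
  responding is faster, more variable and error-prone;
- `msart.metrics` — scoring: error rates, mean RT and RT CV (= SD/mean)
  over the 4 go trials preceding each no-go (with the standard exclusion
  rules), d′ = Z(hit) − Z(FA) with hits = correct withholds and false
  alarms = go omissions, deepest mode/classification, consecutive-error
  runs, and the same battery per 5-minute time window;
- `msart.stats` — one-way and Welch ANOVA with partial η², the rank-based
  two-way Scheirer–Ray–Hare test, Tukey/Games–Howell/Bonferroni post hocs,
  and noncentral-F a-priori sample-size computation;
- a CLI (`msart simulate | analyze | power | sweep | fixtures`) over CSV
  trial logs with JSON sidecars.

## Worked example

Simulate a severely mind-wandering participant, score the session, and run
the a-priori power computation:

```bash
$ msart simulate --seed 7 --preset severe --out severe.csv
wrote severe.csv (1158 trials, deepest mode 9)

$ msart analyze --log severe.csv --out-dir scored
severe: deepest_mode=9 class=severe d_prime=1.024

$ msart power --f 0.25 --alpha 0.05 --power 0.80 --k 3
159
```

The scored table (`scored/metrics.csv`) for this session reads:

| measure | value | meaning |
|---|---|---|
| nogo_error_rate | 0.623 | commissions / no-go stimuli |
| go_error_rate | 0.090 | omissions / go stimuli |
| mean_rt | 304.1 ms | mean over retained pre-no-go 4-RT sets |
| rt_cv | 0.179 | SD/mean per set, averaged (55 sets retained) |
| d_prime | 1.024 | Z(hit) − Z(false alarm) |
| deepest_mode | 9 → severe | max mode at which a stimulus appeared |
| max_consecutive_errors | 14 | longest commission run |

Fast, variable responding with many commission runs drives the mode machine
to 9 — exactly the severe signature. The `power` output says 159 total
participants (53 per group × 3) are the minimum for a one-way ANOVA to
detect f = 0.25 at α = .05 with power .80 under the noncentral-F model.

The same from Python:

```python
from msart import SessionConfig, run_session, MarkovResponder, ResponderParams, score_session

log = run_session(SessionConfig(rng_seed=7), MarkovResponder(ResponderParams(severity=0.75)))
print(score_session(log))
```

A severity sweep (`msart sweep --levels 0.1,0.5,0.9 --reps 50 --seed 1
--out sweep.csv`) recovers the monotone degradation pattern: rising
severity lowers mean RT and d′ while raising RT CV and deepest mode.

See `docs/methods.md` for the model, scoring rules, statistical formulas
and the design choices behind them.

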