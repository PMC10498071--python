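# Methods

## The paradigm

`msart` simulates an adaptive variant of the Sustained Attention to Response
Task (SART). Digits 1–9 appear one at a time (fixation cross 900–1200 ms,
digit 500 ms); every digit except 3 requires a "j" keypress, digit 3 must be
withheld. The task holds a difficulty *mode* m ∈ {1, …, 9}; mode m fixes the
no-go probability at the m-th entry of (1/9, 1/9, 2/9, 3/9, …, 8/9). A no-go
commission error advances the mode by one (capped at 9); a correct no-go
withhold resets it to 1; a "b" correction press immediately after an error
also resets it to 1. Sessions run a fixed 30 minutes, preceded by an
unscored 18-trial practice block containing exactly 2 no-go stimuli.

The logic of the escalation: go responses are highly automatic, so a run of
consecutive no-go commissions — even as the no-go stimuli become frequent
and the task objectively easier — marks a lapse of attention to the task
(mind-wandering). The deepest mode at which a stimulus was presented
therefore grades the lapse: modes 1–3 are classified *mild*, 4–6 *moderate*,
7–9 *severe*. Five consecutive commissions starting from mode 1 put the
sixth no-go at mode 6; a correct withhold there returns the task to mode 1
and leaves a deepest mode of 6 (moderate).

### Engine choices

Open details of the protocol were fixed as follows.

- **Stimulus draws** are per-trial Bernoulli at the current mode's no-go
  probability; no block balancing, since the mode can change on any trial.
  Go digits are uniform over {1, 2, 4, …, 9}.
- **Response window**: a press counts from stimulus onset to the next
  stimulus onset (configurable `response_deadline`); RT is measured from
  onset.
- **"b" semantics**: a correction is effective only immediately after an
  error trial, before the next stimulus. Under the default
  `deepest="presented"` convention, depth is credited only to modes at
  which a stimulus was actually presented, so a prompt correction annuls
  the would-be escalation — consistent with the key's purpose of keeping
  non-lapse slips out of the depth score. `deepest="entered"` credits every
  mode entered. Corrected errors still count in the raw error rates; the
  correction touches only the mode machine and the `corrected` flag.
- **Go omissions** never advance the mode (consecutive errors are no-go
  commissions by definition), but an omission may be b-corrected, which
  resets the consecutive-error counter like any correction.
- Fixation jitter is uniform over integer milliseconds in [900, 1200]. A
  trial starts only if its stimulus onset falls strictly before the session
  end. Mode 9 absorbs further errors (no 10th state).
- Randomness: one session seed, split into four independent substreams
  (jitter, stimulus class, go digit, responder), so a (config, responder,
  seed) triple reproduces a log byte for byte.

## The synthetic responder

The generative participant is deliberately minimal: a two-state Markov
chain over trials, attention ∈ {on-task, off-task}, with per-trial
transition probabilities p_off (on→off) and p_on (off→on). Conditional on
the state the responder commits no-go errors (commit_on < commit_off),
omits go responses (omit_on < omit_off), and draws go/commission RTs from a
lognormal parameterised by a state-specific mean and CV, with off-task
responding faster and more variable (rt_mean_off < rt_mean_on,
rt_cv_off > rt_cv_on). After an error committed while on-task the responder
presses "b" with probability p_correct_b (default 0.5); off-task errors are
never corrected — the key exists to discount slips, not lapses. A scalar
`severity` ∈ [0, 1] interpolates p_off linearly toward a ceiling of 0.5 and
p_on toward a floor of 0.02, so higher severity means wandering more often
and longer; the stationary off-task occupancy is p_off/(p_off + p_on).

Defaults (p_off = 0.02, p_on = 0.40 at severity 0, commit 0.10/0.78, omit
0.02/0.15, RT 335/300 ms, CV 0.15/0.24) were chosen once so that a
mid-severity (0.5) responder in a 30-minute session lands near a no-go
error rate of 0.50, a go error rate of 0.09 and d′ ≈ 1.4 — realistic
magnitudes for this task family — and so that sweeping severity reproduces
the qualitative degradation pattern (mean RT falls, RT CV rises, d′ falls,
deepest mode rises). These are simulator constructs, not estimates from any
human dataset. The model emulates the alternation between attentive and
wandering episodes and its behavioural signatures; it does not emulate
graded depth within an episode, learning/fatigue trends, intentional
mind-wandering, or RT autocorrelation beyond what the two states induce —
so passing tests demonstrate that the paradigm's metrics recover a known
latent process, not that they are valid for humans.

## Scoring

- **Error rates**: commissions / no-go count and omissions / go count; a
  class absent from the log yields an absent rate, not 0.
- **Pre-no-go RT sets**: for each no-go stimulus, the RTs of the 4 go
  trials immediately preceding it. Sets are dropped when anchored at the
  session's first two no-gos, when fewer than 4 go trials separate the
  anchor from the previous no-go, or when any of the 4 go trials was
  omitted (an RT cannot be imputed). Mean RT and RT CV (sample SD / mean,
  n−1 denominator) are computed per set and averaged across sets — the
  4-RT set is the unit of analysis — with a `pooled` alternative that
  pools all retained RTs.
- **d′** = Z(hit) − Z(FA) with hits = correct no-go withholds and false
  alarms = go omissions (the task's mapping of signal-detection roles);
  proportions of exactly 0 or 1 are replaced by 1/(2N) and 1 − 1/(2N).
- **Depth**: deepest mode = max mode at stimulus onset; classification by
  the 1–3/4–6/7–9 bands; consecutive-error runs are maximal runs of
  commissions terminated by a correct withhold or an effective correction
  (the corrected commission still counts inside its run).
- **Time windows**: trials are binned by onset into half-open 300-s windows
  ([0, 300), [300, 600), …; six for a 30-minute session, ceil(T/300)
  otherwise) — the half-open convention partitions the session exactly.
  Pre-no-go sets follow their anchoring no-go's window. Empty windows
  report absent metrics.

## Statistics

- **One-way ANOVA** with partial η² = SS_between/(SS_between + SS_within);
  zero within-variance with equal means gives F = 0 by convention, with
  separated means F = ∞ and η² = 1.
- **Welch ANOVA** with Welch–Satterthwaite fractional denominator df, for
  heteroscedastic groups; zero-variance groups are rejected (the weights
  n_i/s_i² are undefined). When variances and sizes are equal it agrees
  with the classical F.
- **Scheirer–Ray–Hare**: mid-ranks over all N observations; the two-way
  rank sums of squares SS_A, SS_B, SS_AB (cells SS minus main effects) are
  each divided by MS_total = SS_total/(N−1) computed on the tied ranks —
  which is exactly the Kruskal–Wallis tie correction, so with one factor
  constant H_A reduces to the tie-corrected Kruskal–Wallis H. Each H is
  referred to χ² on the effect's df. Results carry (df, N_total), the
  conventional "H(df, N)" reporting pair.
- **Post hoc**: Games–Howell (unequal variances; studentized range on
  Welch df) after Welch's F, Tukey HSD after the classical F, Bonferroni-
  corrected Welch t-tests as a conservative fallback.
- **Power / sample size**: for k equal groups and Cohen's f, power at total
  N is P[F′(k−1, N−k; λ = f²N) > F_crit(α)]. `required_sample_size`
  searches N upward in steps of k (whole equal groups; a per-unit search is
  available via `step=1`). At f = 0.25, α = .05, power = .80, k = 3 the
  equal-allocation search gives N = 159 (the per-unit search gives 158).

p-values are returned exactly; "p < .001"-style formatting is left to the
caller.

## Problem sizes and numerical notes

The test suite simulates 2–10-minute sessions for unit checks and a
3-severity × 50-session sweep of full 30-minute sessions for parameter
recovery (a 30-minute session is ~1,200 trials and simulates in ~15 ms).
Null calibration of the ANOVA p-values uses 1,000 replicates of 3×20
normal samples against a uniform KS test at α = .01. Trial onsets are
rounded to 0.1 ms and RTs to 1 μs in logs; metric equivalence tests compare
at 1e-12 relative tolerance. Seeds derived for sweep cells are masked below
2³¹.

## Known limitations

Session logs store one row per stimulus; within-trial timing of the "b"
press is not modelled beyond its trial-level effect. The responder's
two-state chain cannot produce the paper-style distinction between
intentional and unintentional wandering (unobservable in this paradigm),
and group-level human values are outside the simulator's claims: the stats
layer reproduces the *shape* of the analysis (tests, effect sizes, power),
not empirical group means.
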