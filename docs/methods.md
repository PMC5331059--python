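# Methods

## The task

`gonogo` simulates and analyses a positive-reinforcement auditory go/no-go
detection task run in the animals' home cages, fully automated, with three
mice sharing one waterspout per cage.  Training proceeds in three phases:

1. **Waterspout habituation.**  Water flows for the first 10 s of each 20 s
   trial, with ITIs uniform on 30–300 s, in alternating 90 min on / 90 min
   off blocks, until licking is regular.
2. **Behavioral shaping.**  Each trial is 0.5 s of pre-stimulus silence, a
   1 s tone (6 kHz / 60 dB SPL labels; no audio is synthesised), and a 3 s
   response window.  A lick inside the window opens the water valve for
   2 s.  ITIs are uniform on 5–9 s, trials may only start after a 5 s
   lick-free *quiet period*, and on 10% of trials 0.5 s of free water is
   delivered at window end to keep the animals engaged.  Once the
   first-lick latency distribution peaks inside the response window, free
   water is removed and the window start is progressively delayed by 0.25,
   0.5 and finally 0.75 s.  The interval from trial start to the delayed
   window start is the *early window*; its first lick aborts the reward
   (the tone still plays) and adds a 20 s time-out to the next ITI.
3. **Operant task.**  The tone shrinks to 0.5 s, the window to 2 s, and a
   third of trials are silent *catch trials* with identical window
   geometry, used to estimate false alarms and hence d′.

Because cages on one rack cannot be acoustically isolated, only one cage
runs trials at a time: each of the four cages is active 60 min out of
every 240, tiling the day exactly and giving 6 h of training per cage per
day.  The 12 h dark phase never gates the engine — training is available
around the clock and the mice self-gate by sleeping.

## Outcome classification

Within a trial, the first lick decides the outcome:

| first lick in…       | tone trial | catch trial        |
|----------------------|------------|--------------------|
| early window         | EARLY (time-out) | EARLY_CATCH (time-out) |
| response window      | HIT (2 s water)  | FALSE_ALARM (nothing)  |
| neither              | MISS       | CORRECT_REJECTION  |

Sensitivity is `d′ = Z(hit rate) − Z(fa rate)` with `Z` the
standard-normal inverse CDF; rates of exactly 0 or 1 are replaced by
`1/(2n)` and `1 − 1/(2n)` of the relevant trial count before inversion.
Two denominator conventions are implemented because printed group
statistics in this literature are often ambiguous between them: the
default `per_type` (hits over tone trials, false alarms over catch trials,
earlies over all trials — standard signal detection) and `per_total`
(everything over all trials).  Notably, published per-cage d′ values in
comparable reports are not reproducible from their printed hit/FA
percentages under any single obvious convention (e.g. Z(0.041) − Z(0.005)
≈ 0.84, not 1.1); we therefore expose both conventions rather than forcing
agreement, and use `per_type` for d′.

Free-water trials follow the engagement rule literally: water is delivered
at window end regardless of licking, the trial is classified normally, and
the `rewarded` flag is true.  Licks during reward delivery are recorded
but cannot change an outcome that the first classified lick has already
fixed.

## The virtual mouse

The agent is explicitly synthetic: a phenomenological generative model
that makes the engine and the statistics testable, with no claim of
fitting any real animal.  Per mouse:

* **Wake/sleep** — an alternating renewal process; sleep onsets arrive at
  `sleep_bout_rate` per awake hour (default 4, halved in the dark via
  `dark_activity_gain` = 2), sleep bouts are exponential with mean
  `sleep_bout_duration` = 900 s.  Cagemates share one process (mice in a
  cage tend to sleep together).  This yields awake fractions of ≈ 0.5
  (light) and ≈ 0.67 (dark), ≈ 0.58 averaged over a training day.
* **Spontaneous licking** — Poisson with `baseline_lick_rate` = 0.0012
  licks/s while awake, times the dark gain at night.
* **Detection** — an awake mouse detects a tone with probability
  `p_detect`, attenuated by the required withhold:
  `p_eff = p_detect · exp(−delay / attention_span)` with `attention_span`
  = 1.5 s.  The lapse term is a deliberate modelling choice: enforced
  response delays make the task genuinely harder, which is what produces
  hit rates that are higher at shorter delays.  At delay 0 the term is
  inert, so parameter recovery is exact there.
* **Lick timing** — a detected tone produces one lick at
  `tone_onset + L`, `L ~ LogNormal(median = adapted_delay +
  latency_median, σ = latency_spread)` (0.35 s and 0.3 by default).
  `adapted_delay` tracks the engine's required delay with a first-order
  daily lag (`delay_adaptation_tau` = 2 days).  Fully adapted, the lick
  sits at the response-window start plus a right-skewed latency (any
  positive unimodal family would do; log-normal matches the skewed shape
  of observed first-lick distributions).  While the animal lags a newly
  increased delay, part of the evoked mass falls in the early window and
  is punished — the mechanism behind the transient hit-rate dips and
  early-rate bumps during acquisition.
* **Impulsivity** — an independent per-trial probability of a premature
  lick uniform in the early window (0.012 → 0.005 across learning).
* **Learning** — `p_detect` rises 0.040 → 0.055 and impulsivity falls as
  exponential approaches with `learning_tau` = 1.5 days.
* **Reward drinking** — the rewarded mouse licks at 6 licks/s while the
  valve is open; in habituation an awake mouse drinks with probability
  0.9 after a uniform 0.2–3 s approach delay.

### Default calibration

Defaults were fixed once, from the closed-form rate algebra, to place a
default 15-day cohort in the regime of a well-trained ad-libitum group:
with awake fraction A ≈ 0.58 and cage-level detection
`D = 1 − (1 − p_detect)³ ≈ 0.157`, the final-day hit rate is
`A · D · e^(−0.75/1.5) · (1 − P(L < delay)) ≈ 5%`; catch-trial false
alarms come only from spontaneous licking, `3 · 0.0012 · 2 s · A ≈ 0.4%`;
the early rate (impulsive + spontaneous + residual mistimed evoked licks)
lands near 1.7%, giving hits ≈ 3× earlies and d′ ≈ 1.  The delay schedule
completes within the first week of simulated training and the median
first-lick latency converges to ≈ 1.5–1.6 s from trial onset.

### What the generator does and does not emulate

It emulates spontaneous and circadian licking, sleep, detection with
latency, impulsivity, multi-day learning and cage-level lick interleaving
with ground-truth mouse identity.  It does **not** model satiety or water
balance, within-day motivation drifts, acoustic variables (SNR, frequency,
level — the tone labels are metadata), inter-individual parameter spread
within a cage, or reinforcement-learning-style credit assignment.  Passing
tests therefore demonstrate that the engine and statistics are correct and
that the analysis recovers known generative parameters — not that real
mice behave like the agent.

## Numerical and design choices

* All event times are rounded to a fixed 1 ms grid (lick sensors operate
  at millisecond scale); audits and re-derivations must compare on that
  grid.
* The quiet-period window is treated as *open*, `(t − 5 s, t)`: with a
  closed left edge a lick exactly at `t − 5` would admit no earliest
  valid onset.  Enforcement defers the trial onset (it never resamples
  the ITI), and time-outs accumulate additively when several punishments
  precede one trial.
* The early window starts at trial start, so it includes the pre-stimulus
  silence and, at positive delays, the tone itself: licks during the tone
  are punished as early, not counted as hits.
* Catch trials with early licks get their own label (EARLY_CATCH) and are
  excluded from the false-alarm numerator; a false alarm requires the
  lick to fall inside the catch trial's virtual response window.
* The delay advances at most one step per day, when the daily peak
  first-lick latency (histogram mode, 0.1 s bins; a point mass is its own
  mode; ties resolve to the earliest bin) lies inside the current
  response window.  A cage enters the operant phase after two full days
  at the maximum delay.
* One RNG per cage-engine and per mouse, split from a master seed via
  `numpy` `SeedSequence.spawn` (cage *i* → engine, wake process, mice…),
  with a fixed draw order (ITI → catch flag → free-water flag → per-mouse
  impulsive then evoked licks, mice in id order).  Identical seeds give
  byte-identical logs.
* All cages share one simulation clock; the clock drift of independent
  per-cage controllers is out of scope.
* Pearson p-values use the usual t-transform (two-sided).

## Problem sizes

The shipped checks use desk-scale problems chosen to keep statistical
power high at interactive runtimes: 10,000-trial single-cage sessions for
composition, audit and recovery checks (binomial 99% CIs), a 100×100 rate
grid for the d′ oracle comparison, and the default 15-day, four-cage,
twelve-mouse cohort (~110,000 trials, ≈ 10 s) for the learning-curve
correlations.

## Known limitations

* The habituation phase models drinking with a single approach-delay
  heuristic; its lick fraction is driven almost entirely by the wake/sleep
  process.
* Daily peak-latency estimates use histogram modes and are noisy at low
  trial counts; delay-advancement timing therefore varies by a day or two
  across seeds.
* `per_type` hit rates equal the agent's detection probability only at
  delay 0; at positive delays attention lapses and mistimed evoked licks
  lower the measured hit rate by design.
* Event logs grow ~8 events per trial; multi-month simulations should
  write per-day files (as `gonogo simulate` does) rather than hold events
  in memory.
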