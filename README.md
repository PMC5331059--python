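# gonogo

Simulation and analysis of **automated home-cage auditory go/no-go operant
conditioning** in groups of mice.

Automated home-cage training lets whole cages of mice acquire an auditory
detection task with water rewards and no experimenter handling: a tone
plays, a lick on the waterspout during a (delayed) response window is
rewarded, a premature lick is punished with a time-out, and silent catch
trials measure guessing.  `gonogo` re-implements that training system as a
pure-software artifact for people who build, test or analyse such rigs:

* a **discrete-event trial engine** running the three-phase protocol
  (habituation → shaping → operant task) with all of its timing, reward
  and punishment contingencies;
* a **virtual-mouse model** — spontaneous and circadian licking, sleep,
  tone detection with latency, impulsivity, multi-day learning — that
  stands in for live animals and makes everything testable end to end;
* a **scheduler** for the staggered 60 min / 180 min cage rotation (one
  cage audible at a time, 6 h training per cage per day);
* a versioned **JSONL event-log format** (+ CSV trial tables) that external
  rigs can also export to;
* the **behavioral statistics** used to track acquisition: hit / false
  alarm / early rates under two denominator conventions, sensitivity
  `d′ = Z(hit) − Z(fa)` with the 1/(2n) extreme-rate correction,
  first-lick latency distributions (median and histogram-mode peak),
  lick-rate traces (lick PSTHs) and day-by-day learning curves with
  Pearson correlations.

See `docs/methods.md` for the model, its assumptions and the calibration
of the virtual-mouse defaults.

## Worked example

Simulate the default cohort — 4 cages × 3 mice, 15 training days starting
in the shaping phase — then analyse the event logs:

```bash
gonogo simulate --days 15 --seed 1 --out runs/demo
# simulated 15 day(s), 4 cage(s), 117148 trials
gonogo analyze --in runs/demo --out runs/analysis --plots
```

`analyze` prints (and writes to `runs/analysis/cohort_summary.json`):

```json
{
  "n_trials": 117148,
  "denominator_convention": "per_type",
  "final_day": 14,
  "final_day_summary": {
    "n_cages": 4,
    "mean_hit_rate": 0.0602,
    "mean_early_rate": 0.0208,
    "hit_early_ratio": 2.888,
    "mean_fa_rate": 0.0054,
    "mean_dprime": 1.028
  },
  "r_peak_latency_vs_delay": {"r": 0.826, "p": 0.00015},
  "r_hit_rate_vs_delay":     {"r": -0.412, "p": 0.127}
}
```

Reading these numbers: training is ad libitum, so absolute response rates
are low — mice sleep through many trials and a missed trial costs little —
but the mice clearly detect the tone: on the final day they respond to 6.0%
of tones while licking on only 0.5% of silent catch trials (`d′ ≈ 1.0`),
and hits are ~3× more frequent than punished early licks.  Across days the
peak first-lick latency shifts together with the experimenter-imposed
response delay (r = 0.83): the animals learn to wait.  Hit rates are lower
on days with longer required delays (r = −0.41): withholding makes the
task harder.  `session_summary.csv` holds per-cage/day rates and
`learning_curve.csv` the day-by-day curve behind the correlations.

Everything is reproducible: `--seed` drives engine and agents through a
documented `SeedSequence` split, identical seeds give byte-identical event
logs, and each run writes a `manifest.json` with the config hash and seed.

A commented protocol file ships in `examples/protocol.yaml`; pass it via
`gonogo simulate --config` to change any phase parameter, the cage
rotation or the virtual-mouse model.

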