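# Example protocol configuration.
#
# Every field is optional: omitted fields take the built-in defaults of the
# three-phase training paradigm, so an empty file is itself a valid config.
# Durations are seconds unless the comment says otherwise.

version: 1           # config dialect version (required to be 1)
phase: shaping       # habituation | shaping | operant
mice_per_cage: 3

habituation:
  trial_duration: 20.0     # water trial length
  water_on_duration: 10.0  # free water flows for the first 10 s
  iti_range: [30.0, 300.0]
  on_block: 90.0           # minutes of trials ...
  off_block: 90.0          # ... then minutes of rest, cyclically

shaping:
  pre_stim_silence: 0.5
  tone_duration: 1.0
  tone_freq: 6000.0        # Hz -- metadata label, no audio is produced
  tone_level: 60.0         # dB SPL -- metadata label
  response_window_duration: 3.0
  response_delay: 0.0      # start of the delay schedule
  iti_range: [5.0, 9.0]
  quiet_period: 5.0        # required lick-free time before trial onset
  reward_duration: 2.0
  free_water_fraction: 0.1 # engagement water on 10% of trials
  free_water_duration: 0.5
  timeout_duration: 20.0   # added to the ITI after an early lick
  catch_fraction: 0.0

operant:
  tone_duration: 0.5
  response_window_duration: 2.0
  response_delay: 0.75
  free_water_fraction: 0.0
  catch_fraction: 0.3333333333333333  # silent catch trials, 1/3 of trials

delay_schedule:
  steps: [0.0, 0.25, 0.5, 0.75]

cage_schedule:
  n_cages: 4
  active_block: 60.0       # minutes; one cage trains at a time
  inactive_block: 180.0    # minutes
  dark_cycle: [18.0, 6.0]  # hour-of-day bounds of the 12 h dark phase

agent:                     # virtual-mouse model (synthetic, per mouse)
  baseline_lick_rate: 0.0012   # spontaneous licks/s while awake (light)
  dark_activity_gain: 2.0
  sleep_bout_rate: 4.0         # sleep onsets per awake hour (light)
  sleep_bout_duration: 900.0   # mean sleep bout, s
  p_detect_initial: 0.04
  p_detect_final: 0.055
  learning_tau: 1.5            # days
  latency_median: 0.35         # s past the response-window start
  latency_spread: 0.3          # sigma of the log-latency
  impulsivity_initial: 0.012
  impulsivity_final: 0.005
  delay_adaptation_tau: 2.0    # days for lick timing to track the delay
  attention_span: 1.5          # s; detection decays exp(-delay/span)
  drink_lick_rate: 6.0
  habituation_drink_prob: 0.9
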