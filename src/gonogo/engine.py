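"""Discrete-event trial engine for one cage's training session.

The engine owns the task contingencies:

* ITIs are drawn uniformly from the configured range, plus one 20 s time-out
  per pending punishment (time-outs accumulate additively);
* a trial may only start after a lick-free quiet period (5 s by default);
  enforcement *defers* the trial onset rather than resampling the ITI;
* each trial is a 0.5 s pre-stimulus silence, a tone (absent on silent
  catch trials, which keep identical window geometry), an **early window**
  from trial start to the delayed response-window start, and the **response
  window** itself;
* the first lick in the early window makes the trial EARLY (EARLY_CATCH on
  catch trials): the tone still plays, no water is delivered, and a time-out
  is added to the next ITI.  Otherwise a response-window lick is a HIT
  (rewarded with 2 s of water) or, on a catch trial, a FALSE_ALARM
  (unrewarded, unpunished).  Trials with no lick in either window are MISS
  or CORRECT_REJECTION;
* on free-water trials (shaping) water is delivered for 0.5 s at the end of
  the response window regardless of licking; the trial is still classified
  normally;
* the response delay advances one schedule step per day once the daily peak
  first-lick latency has shifted into the current response window.

All event times are kept on a 1 ms grid.  A single seeded RNG drives the
engine with a fixed draw order (ITI, then catch flag, then free-water flag
on non-catch trials), so identical seeds give byte-identical logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .agent import CageAgents
from .config import DelaySchedule, DetectionPhaseConfig, ProtocolConfig
from .events import EventRecord
from .schedule import habituation_block_active, next_habituation_block_start

#: trial outcome labels
HIT = "HIT"
MISS = "MISS"
EARLY = "EARLY"
FALSE_ALARM = "FALSE_ALARM"
CORRECT_REJECTION = "CORRECT_REJECTION"
EARLY_CATCH = "EARLY_CATCH"
TONE_LABELS = (HIT, MISS, EARLY)
CATCH_LABELS = (FALSE_ALARM, CORRECT_REJECTION, EARLY_CATCH)

_EVENT_PRIORITY = {
    "SESSION_START": 0,
    "PHASE_CHANGE": 1,
    "CAGE_ACTIVE": 2,
    "TRIAL_START": 3,
    "TONE_ON": 4,
    "TONE_OFF": 5,
    "LICK": 6,
    "REWARD_ON": 7,
    "REWARD_OFF": 8,
    "TIMEOUT_START": 9,
    "TRIAL_END": 10,
    "CAGE_INACTIVE": 11,
}


def _round3(x: float) -> float:
    return round(float(x), 3)


@dataclass
class TrialSpec:
    """Geometry of one trial on the session clock (seconds).

    ``early_window = [t_start, early_end)`` ends exactly where
    ``response_window = [early_end, response_end)`` begins; catch trials
    carry the same geometry with a virtual tone onset.
    """

    trial_id: int
    t_start: float
    is_catch: bool
    free_water: bool
    delay: float
    tone_onset: float
    tone_offset: float
    early_end: float
    response_end: float

    @property
    def early_window(self) -> Tuple[float, float]:
        return (self.t_start, self.early_end)

    @property
    def response_window(self) -> Tuple[float, float]:
        return (self.early_end, self.response_end)


@dataclass
class TrialOutcome:
    label: str
    first_lick_latency: Optional[float]
    rewarded: bool
    timeout_applied: bool


@dataclass
class EngineState:
    """Mutable per-session engine state."""

    phase: str
    current_delay: float
    pending_timeouts: int = 0
    last_lick_time: Optional[float] = None
    trial_counter: int = 0
    clock: float = 0.0


@dataclass
class SessionResult:
    events: List[EventRecord]
    trials: List[dict]
    state: EngineState


# ---------------------------------------------------------------------------
# elementary operations


def sample_iti(config, pending_timeouts: int, rng: np.random.Generator) -> float:
    """Uniform ITI plus one full time-out per pending punishment."""
    lo, hi = config.iti_range
    u = float(rng.uniform(lo, hi))
    timeout = getattr(config, "timeout_duration", 0.0)
    return u + timeout * pending_timeouts


def enforce_quiet_period(
    candidate_onset: float,
    lick_times: Sequence[float],
    quiet_period: float,
    horizon: float = math.inf,
) -> Optional[float]:
    """Earliest ``t >= candidate_onset`` with no lick in ``(t - quiet, t)``.

    ``lick_times`` must be sorted ascending.  Returns ``None`` (deferred)
    when the required quiet window extends past ``horizon``, i.e. the
    supplied lick stream cannot yet prove the animal has stopped licking;
    the caller re-evaluates as the stream grows.
    """
    t = candidate_onset
    for lick in lick_times:
        if lick >= t:
            break
        if lick > t - quiet_period:
            t = lick + quiet_period
    return t if t <= horizon else None


def build_trial(
    state: EngineState, config: DetectionPhaseConfig, rng: np.random.Generator
) -> TrialSpec:
    """Construct the next trial at ``state.clock`` and advance the counter.

    Draw order: catch flag, then (non-catch only) the free-water flag.
    """
    t0 = _round3(state.clock)
    is_catch = bool(rng.random() < config.catch_fraction)
    free_water = (not is_catch) and bool(rng.random() < config.free_water_fraction)
    tone_onset = _round3(t0 + config.pre_stim_silence)
    spec = TrialSpec(
        trial_id=state.trial_counter,
        t_start=t0,
        is_catch=is_catch,
        free_water=free_water,
        delay=state.current_delay,
        tone_onset=tone_onset,
        tone_offset=_round3(tone_onset + config.tone_duration),
        early_end=_round3(tone_onset + state.current_delay),
        response_end=_round3(
            tone_onset + state.current_delay + config.response_window_duration
        ),
    )
    state.trial_counter += 1
    return spec


def classify_trial(spec: TrialSpec, lick_times: Sequence[float]) -> TrialOutcome:
    """Apply the outcome contingencies to one trial's lick times.

    ``lick_times`` are session-clock seconds within the trial, sorted
    ascending; licks after the response window (e.g. during reward
    delivery) are permitted and do not change the label.
    """
    licks = list(lick_times)
    if any(b < a for a, b in zip(licks, licks[1:])):
        raise ValueError("lick_times must be sorted ascending")
    if licks and licks[0] < spec.t_start:
        raise ValueError("lick before trial start")

    first_early = next((t for t in licks if spec.t_start <= t < spec.early_end), None)
    if first_early is not None:
        label = EARLY_CATCH if spec.is_catch else EARLY
    elif any(spec.early_end <= t < spec.response_end for t in licks):
        label = FALSE_ALARM if spec.is_catch else HIT
    else:
        label = CORRECT_REJECTION if spec.is_catch else MISS

    latency = _round3(licks[0] - spec.t_start) if licks else None
    return TrialOutcome(
        label=label,
        first_lick_latency=latency,
        rewarded=(label == HIT) or spec.free_water,
        timeout_applied=label in (EARLY, EARLY_CATCH),
    )


def maybe_advance_delay(
    daily_peak_latency: Optional[float],
    config: DetectionPhaseConfig,
    current_delay: float,
    schedule: DelaySchedule,
) -> float:
    """Next response delay given today's peak first-lick latency.

    The delay is increased one step when the peak latency (relative to
    trial start) has shifted into the current response window; it never
    exceeds the schedule's maximum.
    """
    if daily_peak_latency is None or not math.isfinite(daily_peak_latency):
        return current_delay
    w0 = config.pre_stim_silence + current_delay
    w1 = w0 + config.response_window_duration
    if w0 <= daily_peak_latency < w1 and current_delay < schedule.max_delay:
        return schedule.next_step(current_delay)
    return current_delay


# ---------------------------------------------------------------------------
# session execution


class _SpontBuffer:
    """Time-ordered buffer of spontaneous cage licks, generated on demand."""

    def __init__(self, cage: CageAgents, t0: float) -> None:
        self.cage = cage
        self.horizon = t0
        self._buf: List[Tuple[float, int]] = []
        self._i = 0

    def ensure(self, until: float) -> None:
        if until > self.horizon:
            self._buf.extend(self.cage.spontaneous_licks(self.horizon, until))
            self.horizon = until

    def pending_times(self) -> List[float]:
        return [t for t, _ in self._buf[self._i :]]

    def take(self, until: float) -> List[Tuple[float, int]]:
        """Pop buffered licks with t < until (must be <= horizon)."""
        out = []
        while self._i < len(self._buf) and self._buf[self._i][0] < until:
            out.append(self._buf[self._i])
            self._i += 1
        return out


def _ev(t, cage_id, event_type, mouse_id=None, trial_id=None, **payload) -> EventRecord:
    return EventRecord(
        t=_round3(t),
        cage_id=cage_id,
        event_type=event_type,
        mouse_id=mouse_id,
        trial_id=trial_id,
        payload=payload,
    )


def run_session(
    protocol: ProtocolConfig,
    cage: CageAgents,
    *,
    rng: np.random.Generator,
    cage_id: int = 0,
    t_start: float = 0.0,
    duration: Optional[float] = None,
    day_index: int = 0,
    phase: Optional[str] = None,
    delay: Optional[float] = None,
    detection_config: Optional[DetectionPhaseConfig] = None,
    max_trials: Optional[int] = None,
    trial_id_start: int = 0,
) -> SessionResult:
    """Run one cage's session and return its event log and trial table.

    ``duration`` may be ``None`` when ``max_trials`` bounds the session.
    ``delay`` overrides the phase config's response delay (the engine's
    current position on the delay schedule); ``detection_config`` replaces
    the phase parameters wholesale (used e.g. to drop free water once
    delays are introduced).
    """
    phase = phase or protocol.phase
    if duration is None and max_trials is None:
        raise ValueError("need duration and/or max_trials")
    session_end = math.inf if duration is None else t_start + duration

    if phase == "habituation":
        return _run_habituation(
            protocol, cage, rng=rng, cage_id=cage_id, t_start=t_start,
            session_end=session_end, day_index=day_index,
            max_trials=max_trials, trial_id_start=trial_id_start,
        )

    cfg = detection_config if detection_config is not None else protocol.detection(phase)
    if delay is not None and delay != cfg.response_delay:
        cfg = cfg.model_copy(update={"response_delay": delay})
    state = EngineState(
        phase=phase, current_delay=cfg.response_delay,
        trial_counter=trial_id_start, clock=t_start,
    )
    span = cfg.pre_stim_silence + cfg.response_delay + cfg.response_window_duration

    events: List[EventRecord] = [
        _ev(t_start, cage_id, "SESSION_START", phase=phase, day_index=day_index,
            delay=cfg.response_delay),
        _ev(t_start, cage_id, "CAGE_ACTIVE"),
    ]
    trials: List[dict] = []
    buf = _SpontBuffer(cage, t_start)
    recent_licks: List[float] = []  # any-source licks, for quiet-period checks
    n_trials = 0

    while max_trials is None or n_trials < max_trials:
        iti = sample_iti(cfg, state.pending_timeouts, rng)
        state.pending_timeouts = 0
        candidate = _round3(state.clock + iti)
        if candidate + span > session_end:
            break
        buf.ensure(candidate)

        # defer the onset until a full quiet period is observed
        onset: Optional[float] = None
        while True:
            known = sorted(recent_licks + buf.pending_times())
            onset = enforce_quiet_period(candidate, known, cfg.quiet_period,
                                         horizon=buf.horizon)
            if onset is not None:
                break
            if buf.horizon >= session_end:
                break
            buf.ensure(min(buf.horizon + 30.0, session_end))
        if onset is None or onset + span > session_end:
            break

        # dispatch ITI licks that precede the trial
        for t, m in buf.take(onset):
            events.append(_ev(t, cage_id, "LICK", mouse_id=m))
            recent_licks.append(t)
            state.last_lick_time = t

        state.clock = onset
        spec = build_trial(state, cfg, rng)
        buf.ensure(spec.response_end)
        trial_licks = buf.take(spec.response_end)
        trial_licks.extend(cage.trial_licks(spec))
        trial_licks.sort()

        outcome = classify_trial(spec, [t for t, _ in trial_licks])

        trial_events: List[EventRecord] = [
            _ev(spec.t_start, cage_id, "TRIAL_START", trial_id=spec.trial_id,
                is_catch=spec.is_catch, free_water=spec.free_water,
                delay=spec.delay, phase=phase, day_index=day_index,
                tone_onset=spec.tone_onset, early_end=spec.early_end,
                response_end=spec.response_end),
        ]
        if not spec.is_catch:
            trial_events.append(_ev(spec.tone_onset, cage_id, "TONE_ON",
                                    trial_id=spec.trial_id))
            trial_events.append(_ev(spec.tone_offset, cage_id, "TONE_OFF",
                                    trial_id=spec.trial_id))

        trial_end = spec.response_end
        if outcome.label == HIT:
            first_rw = next(
                (t, m) for t, m in trial_licks if spec.early_end <= t < spec.response_end
            )
            reward_on, drinker = first_rw
            reward_off = _round3(reward_on + cfg.reward_duration)
            trial_events.append(_ev(reward_on, cage_id, "REWARD_ON",
                                    trial_id=spec.trial_id, kind="hit"))
            trial_events.append(_ev(reward_off, cage_id, "REWARD_OFF",
                                    trial_id=spec.trial_id))
            for t in cage.mouse(drinker).drink_licks(reward_on, reward_off):
                trial_licks.append((t, drinker))
            trial_end = max(trial_end, reward_off)
        if spec.free_water:
            fw_on = spec.response_end
            fw_off = _round3(fw_on + cfg.free_water_duration)
            trial_events.append(_ev(fw_on, cage_id, "REWARD_ON",
                                    trial_id=spec.trial_id, kind="free_water"))
            trial_events.append(_ev(fw_off, cage_id, "REWARD_OFF",
                                    trial_id=spec.trial_id))
            trial_end = max(trial_end, fw_off)
        if outcome.timeout_applied:
            trial_events.append(_ev(spec.response_end, cage_id, "TIMEOUT_START",
                                    trial_id=spec.trial_id,
                                    duration=cfg.timeout_duration))
            state.pending_timeouts += 1

        # spontaneous licks that fall in the reward tail still belong here
        buf.ensure(trial_end)
        trial_licks.extend(buf.take(trial_end))
        trial_licks.sort()
        for t, m in trial_licks:
            trial_events.append(_ev(t, cage_id, "LICK", mouse_id=m,
                                    trial_id=spec.trial_id))
            recent_licks.append(t)
            state.last_lick_time = t

        # latency must reflect the full lick list (a reward-tail lick can be
        # the first lick on a free-water miss trial)
        all_times = [t for t, _ in trial_licks]
        if all_times and (outcome.first_lick_latency is None):
            outcome.first_lick_latency = _round3(all_times[0] - spec.t_start)

        trial_events.append(_ev(trial_end, cage_id, "TRIAL_END",
                                trial_id=spec.trial_id, outcome=outcome.label,
                                first_lick_latency=outcome.first_lick_latency,
                                rewarded=outcome.rewarded,
                                timeout_applied=outcome.timeout_applied,
                                n_licks=len(trial_licks)))
        trial_events.sort(key=lambda e: (e.t, _EVENT_PRIORITY[e.event_type]))
        events.extend(trial_events)

        trials.append(_trial_row(cage_id, day_index, phase, spec, outcome,
                                 [t for t, _ in trial_licks]))
        state.clock = trial_end
        recent_licks = [t for t in recent_licks if t > trial_end - cfg.quiet_period]
        n_trials += 1

    # trailing ITI licks
    tail_end = session_end if math.isfinite(session_end) else state.clock
    buf.ensure(tail_end)
    for t, m in buf.take(tail_end):
        events.append(_ev(t, cage_id, "LICK", mouse_id=m))
        state.last_lick_time = t
    events.append(_ev(tail_end, cage_id, "CAGE_INACTIVE"))
    state.clock = tail_end
    return SessionResult(events=events, trials=trials, state=state)


def _trial_row(cage_id, day_index, phase, spec: TrialSpec, outcome: TrialOutcome,
               lick_times: List[float]) -> dict:
    return {
        "cage_id": cage_id,
        "trial_id": spec.trial_id,
        "day_index": day_index,
        "phase": phase,
        "t_start": spec.t_start,
        "is_catch": spec.is_catch,
        "free_water": spec.free_water,
        "delay": spec.delay,
        "tone_onset": spec.tone_onset,
        "early_end": spec.early_end,
        "response_end": spec.response_end,
        "outcome": outcome.label,
        "first_lick_latency": outcome.first_lick_latency,
        "rewarded": outcome.rewarded,
        "timeout_applied": outcome.timeout_applied,
        "n_licks": len(lick_times),
        "lick_times": tuple(_round3(t - spec.t_start) for t in lick_times),
    }


def _run_habituation(
    protocol: ProtocolConfig,
    cage: CageAgents,
    *,
    rng: np.random.Generator,
    cage_id: int,
    t_start: float,
    session_end: float,
    day_index: int,
    max_trials: Optional[int],
    trial_id_start: int,
) -> SessionResult:
    """Habituation: timed free-water trials, no stimulus, 90/90 min blocks.

    Block phase is measured from the session epoch (t = 0).  No quiet
    period is enforced and nothing is punished; a mouse that is awake
    simply drinks while the water is on.
    """
    cfg = protocol.habituation
    params = cage.mice[0].params
    state = EngineState(phase="habituation", current_delay=0.0,
                        trial_counter=trial_id_start, clock=t_start)
    events: List[EventRecord] = [
        _ev(t_start, cage_id, "SESSION_START", phase="habituation",
            day_index=day_index),
        _ev(t_start, cage_id, "CAGE_ACTIVE"),
    ]
    trials: List[dict] = []
    buf = _SpontBuffer(cage, t_start)
    n_trials = 0

    while max_trials is None or n_trials < max_trials:
        iti = sample_iti(cfg, 0, rng)
        onset = _round3(state.clock + iti)
        if not habituation_block_active(cfg, onset):
            resume = next_habituation_block_start(cfg, onset)
            buf.ensure(min(resume, session_end))
            for t, m in buf.take(min(resume, session_end)):
                events.append(_ev(t, cage_id, "LICK", mouse_id=m))
            state.clock = resume
            if resume >= session_end:
                break
            continue
        trial_end = _round3(onset + cfg.trial_duration)
        if trial_end > session_end:
            break

        buf.ensure(onset)
        for t, m in buf.take(onset):
            events.append(_ev(t, cage_id, "LICK", mouse_id=m))

        water_off = _round3(onset + cfg.water_on_duration)
        trial_id = state.trial_counter
        state.trial_counter += 1
        buf.ensure(trial_end)
        trial_licks = buf.take(trial_end)

        drinker = cage.first_awake(onset)
        if drinker is not None and drinker.rng.random() < params.habituation_drink_prob:
            approach = float(drinker.rng.uniform(0.2, 3.0))
            for t in drinker.drink_licks(onset + approach, water_off):
                trial_licks.append((t, drinker.mouse_id))
        trial_licks.sort()

        licked = any(onset <= t < trial_end for t, _ in trial_licks)
        trial_events = [
            _ev(onset, cage_id, "TRIAL_START", trial_id=trial_id,
                phase="habituation", day_index=day_index,
                trial_duration=cfg.trial_duration),
            _ev(onset, cage_id, "REWARD_ON", trial_id=trial_id, kind="habituation"),
            _ev(water_off, cage_id, "REWARD_OFF", trial_id=trial_id),
        ]
        for t, m in trial_licks:
            trial_events.append(_ev(t, cage_id, "LICK", mouse_id=m, trial_id=trial_id))
        first = trial_licks[0][0] if trial_licks else None
        trial_events.append(_ev(trial_end, cage_id, "TRIAL_END", trial_id=trial_id,
                                outcome="LICKED" if licked else "NO_LICK",
                                first_lick_latency=(_round3(first - onset)
                                                    if first is not None else None),
                                rewarded=True, timeout_applied=False,
                                n_licks=len(trial_licks)))
        trial_events.sort(key=lambda e: (e.t, _EVENT_PRIORITY[e.event_type]))
        events.extend(trial_events)

        trials.append({
            "cage_id": cage_id, "trial_id": trial_id, "day_index": day_index,
            "phase": "habituation", "t_start": onset, "is_catch": False,
            "free_water": True, "delay": float("nan"),
            "tone_onset": float("nan"), "early_end": float("nan"),
            "response_end": trial_end,
            "outcome": "LICKED" if licked else "NO_LICK",
            "first_lick_latency": _round3(first - onset) if first is not None else None,
            "rewarded": True, "timeout_applied": False,
            "n_licks": len(trial_licks),
            "lick_times": tuple(_round3(t - onset) for t, _ in trial_licks),
        })
        state.clock = trial_end
        n_trials += 1

    tail_end = session_end if math.isfinite(session_end) else state.clock
    buf.ensure(tail_end)
    for t, m in buf.take(tail_end):
        events.append(_ev(t, cage_id, "LICK", mouse_id=m))
    events.append(_ev(tail_end, cage_id, "CAGE_INACTIVE"))
    state.clock = tail_end
    return SessionResult(events=events, trials=trials, state=state)
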