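"""Parametric generative model of mouse licking behavior.

This is an explicitly *synthetic* stand-in for live animals: a small
phenomenological model whose purpose is to exercise the trial engine and the
analysis suite under realistic-looking conditions, not to fit any real
mouse.  It emulates four features of home-cage behavior:

* **spontaneous licking** -- an inhomogeneous Poisson process on the
  waterspout, gated by an alternating wake/sleep renewal process and
  modulated by the light/dark cycle (mice are nocturnal);
* **tone detection with latency** -- on a tone trial an awake mouse emits a
  single tone-evoked lick with probability ``p_detect``; the lick time is
  log-normal around a timing target that the animal learns;
* **impulsivity** -- a per-trial probability of a premature lick uniformly
  placed in the early window;
* **multi-day learning** -- ``p_detect`` rises and impulsivity falls as
  exponential approaches with time constant ``learning_tau`` (days), and the
  lick-timing target tracks the engine's required response delay with its
  own lag (``delay_adaptation_tau``), so the first-lick latency distribution
  shifts with the response window across days.

Two deliberate generative choices shape the learning curves.  First, the
evoked-lick time is anchored to tone onset at
``LogNormal(median = adapted_delay + latency_median, sigma = latency_spread)``;
while ``adapted_delay`` lags the required delay, part of the evoked mass
falls in the early window and is punished, which transiently depresses hit
rates after every delay increase.  Once adapted, the lick sits at the
response-window start plus the log-normal latency.  Second, detection is
attenuated by the required withhold: ``p_eff = p_detect * exp(-delay /
attention_span)``, so the task is genuinely harder at longer delays.  At
delay 0 both mechanisms are inert and the hit rate recovers ``p_detect``
exactly (parameter recovery).

A cage is a set of mice sharing one waterspout; their licks interleave in
the event log with individual identity retained.  Cagemates share one
wake/sleep process by default (mice in a cage tend to sleep together).
"""

from __future__ import annotations

import bisect
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field

from . import schedule as _sched
from .schedule import CageSchedule


class AgentParams(BaseModel):
    """Virtual-mouse parameters.  Rates are per second, taus in days.

    Defaults describe one mouse in a three-mouse cage and were chosen so
    that a default 15-day cohort lands in the regime of a well-trained but
    ad-libitum group: final-day hit rates of a few percent, near-zero false
    alarms, hits roughly three times more frequent than early responses,
    and d-prime near 1 (see the methods note for the arithmetic).
    """

    baseline_lick_rate: float = Field(default=0.0012, ge=0.0)
    dark_activity_gain: float = Field(default=2.0, ge=0.0)
    sleep_bout_rate: float = Field(default=4.0, ge=0.0)  # sleep onsets per awake hour (light)
    sleep_bout_duration: float = Field(default=900.0, gt=0.0)  # mean s asleep
    p_detect_initial: float = Field(default=0.040, ge=0.0, le=1.0)
    p_detect_final: float = Field(default=0.055, ge=0.0, le=1.0)
    learning_tau: float = Field(default=1.5, gt=0.0)
    latency_median: float = Field(default=0.35, gt=0.0)  # s beyond the window start
    latency_spread: float = Field(default=0.30, ge=0.0)  # sigma of log-latency
    impulsivity_initial: float = Field(default=0.012, ge=0.0, le=1.0)
    impulsivity_final: float = Field(default=0.005, ge=0.0, le=1.0)
    delay_adaptation_tau: float = Field(default=2.0, gt=0.0)
    attention_span: float = Field(default=1.5, gt=0.0)  # s; detection lapse scale
    drink_lick_rate: float = Field(default=6.0, ge=0.0)  # licks/s while water flows
    habituation_drink_prob: float = Field(default=0.9, ge=0.0, le=1.0)
    seed: Optional[int] = None


def _round3(x: float) -> float:
    return round(float(x), 3)


class WakeSleepProcess:
    """Alternating wake/sleep renewal process, queryable in time order.

    While awake the hazard of falling asleep is ``sleep_bout_rate / 3600``
    per second, divided by ``dark_activity_gain`` during the dark phase
    (longer wake bouts at night).  Sleep bouts are exponential with mean
    ``sleep_bout_duration``.  ``sleep_bout_rate = 0`` gives a mouse that
    never sleeps and consumes no randomness.
    """

    def __init__(
        self,
        params: AgentParams,
        rng: np.random.Generator,
        cage_schedule: Optional[CageSchedule] = None,
        t0: float = 0.0,
        start_awake: bool = True,
    ) -> None:
        self.params = params
        self.rng = rng
        self.schedule = cage_schedule
        self._start_awake = start_awake
        self._transitions: List[float] = []  # state flips after t0
        self._cursor = t0
        self._cursor_awake = start_awake

    def _is_dark(self, t: float) -> bool:
        return self.schedule is not None and _sched.is_dark(self.schedule, t)

    def _advance(self, until: float) -> None:
        p = self.params
        while self._cursor < until:
            if self._cursor_awake:
                hazard = p.sleep_bout_rate / 3600.0
                if hazard > 0 and self._is_dark(self._cursor):
                    hazard /= max(p.dark_activity_gain, 1e-12)
                if hazard <= 0:
                    self._cursor = until
                    return
                dur = self.rng.exponential(1.0 / hazard)
            else:
                dur = self.rng.exponential(p.sleep_bout_duration)
            self._cursor += dur
            self._transitions.append(self._cursor)
            self._cursor_awake = not self._cursor_awake

    def awake_at(self, t: float) -> bool:
        self._advance(t)
        n_flips = bisect.bisect_right(self._transitions, t)
        return self._start_awake if n_flips % 2 == 0 else not self._start_awake

    def wake_intervals(self, t0: float, t1: float) -> List[Tuple[float, float]]:
        """Awake sub-intervals of ``[t0, t1)``, in order."""
        if t1 <= t0:
            return []
        self._advance(t1)
        out: List[Tuple[float, float]] = []
        i = bisect.bisect_right(self._transitions, t0)
        awake = self._start_awake if i % 2 == 0 else not self._start_awake
        t = t0
        while t < t1:
            nxt = self._transitions[i] if i < len(self._transitions) else math.inf
            seg_end = min(nxt, t1)
            if awake and seg_end > t:
                out.append((t, seg_end))
            t = seg_end
            awake = not awake
            i += 1
        return out


class VirtualMouse:
    """One synthetic mouse: spontaneous licking plus task behavior.

    Mutable learning state: ``p_detect``, ``impulsivity`` (updated by
    :meth:`update_learning`) and ``adapted_delay`` (updated by
    :meth:`adapt_to_delay`, once per training day).
    """

    def __init__(
        self,
        params: AgentParams,
        mouse_id: int,
        rng: np.random.Generator,
        wake: Optional[WakeSleepProcess] = None,
        cage_schedule: Optional[CageSchedule] = None,
    ) -> None:
        self.params = params
        self.mouse_id = mouse_id
        self.rng = rng
        self.schedule = cage_schedule
        self.wake = wake if wake is not None else WakeSleepProcess(params, rng, cage_schedule)
        self.day_index = 0
        self.p_detect = params.p_detect_initial
        self.impulsivity = params.impulsivity_initial
        self.adapted_delay = 0.0

    # -- learning -----------------------------------------------------------

    def update_learning(self, day_index: int) -> "VirtualMouse":
        """Set learning state for ``day_index`` (0 = first training day).

        ``p_detect(d) = final + (initial - final) * exp(-d / tau)``; the
        impulsive-lick probability follows the same form and decreases.
        """
        if day_index < self.day_index:
            raise ValueError("day_index must be non-decreasing")
        p = self.params
        decay = math.exp(-day_index / p.learning_tau)
        self.p_detect = p.p_detect_final + (p.p_detect_initial - p.p_detect_final) * decay
        self.impulsivity = (
            p.impulsivity_final + (p.impulsivity_initial - p.impulsivity_final) * decay
        )
        self.day_index = day_index
        return self

    def adapt_to_delay(self, delay: float) -> None:
        """One day's worth of adaptation of the lick-timing target."""
        alpha = 1.0 - math.exp(-1.0 / self.params.delay_adaptation_tau)
        self.adapted_delay += alpha * (delay - self.adapted_delay)

    # -- behavior -----------------------------------------------------------

    def spontaneous_licks(self, t0: float, t1: float) -> List[float]:
        """Poisson licks strictly inside ``(t0, t1)``, sorted, 1 ms grid."""
        if t1 <= t0:
            return []
        p = self.params
        if p.baseline_lick_rate <= 0:
            # still advance the shared wake process deterministically
            self.wake._advance(t1)
            return []
        times: List[float] = []
        for a, b in self.wake.wake_intervals(t0, t1):
            # split at light/dark boundaries so the dark gain applies cleanly
            seg = a
            while seg < b:
                dark = self._dark(seg)
                nxt = min(b, self._next_light_boundary(seg))
                rate = p.baseline_lick_rate * (p.dark_activity_gain if dark else 1.0)
                n = int(self.rng.poisson(rate * (nxt - seg)))
                if n:
                    times.extend(self.rng.uniform(seg, nxt, size=n).tolist())
                seg = nxt
        times = sorted(_round3(t) for t in times)
        return [t for t in times if t0 < t < t1]

    def _dark(self, t: float) -> bool:
        return self.schedule is not None and _sched.is_dark(self.schedule, t)

    def _next_light_boundary(self, t: float) -> float:
        if self.schedule is None:
            return math.inf
        start, end = self.schedule.dark_cycle
        hour = (t / 3600.0) % 24.0
        deltas = [(h - hour) % 24.0 for h in (start, end)]
        step = min(d for d in deltas if d > 1e-9)
        return t + step * 3600.0

    def tone_response(self, spec) -> Optional[float]:
        """Tone-evoked lick time for a tone trial, or None.

        Raises ``ValueError`` on catch trials: there is no tone to detect.
        Detection requires the mouse to be awake at tone onset; the
        effective detection probability is attenuated by the required
        delay (sustained-attention lapse).
        """
        if spec.is_catch:
            raise ValueError("tone_response called on a catch trial")
        if not self.wake.awake_at(spec.tone_onset):
            return None
        p = self.params
        p_eff = self.p_detect * math.exp(-spec.delay / p.attention_span)
        if self.rng.random() >= p_eff:
            return None
        median = self.adapted_delay + p.latency_median
        if p.latency_spread > 0:
            lat = median * math.exp(self.rng.normal(0.0, p.latency_spread))
        else:
            lat = median
        t = _round3(spec.tone_onset + lat)
        return t if t < spec.response_end else None

    def early_lick(self, spec) -> Optional[float]:
        """Impulsive premature lick uniformly in the early window, or None."""
        if self.impulsivity <= 0 or spec.early_end <= spec.t_start:
            return None
        if not self.wake.awake_at(spec.t_start):
            return None
        if self.rng.random() < self.impulsivity:
            return _round3(self.rng.uniform(spec.t_start, spec.early_end))
        return None

    def drink_licks(self, t0: float, t1: float) -> List[float]:
        """High-rate licking while the water valve is open."""
        if t1 <= t0 or self.params.drink_lick_rate <= 0:
            return []
        n = int(self.rng.poisson(self.params.drink_lick_rate * (t1 - t0)))
        times = sorted(_round3(t) for t in self.rng.uniform(t0, t1, size=n))
        return [t for t in times if t0 < t < t1]


class CageAgents:
    """A cage: several mice sharing one waterspout (and one sleep rhythm)."""

    def __init__(self, mice: Sequence[VirtualMouse]) -> None:
        if not mice:
            raise ValueError("a cage needs at least one mouse")
        self.mice = list(mice)

    @classmethod
    def from_params(
        cls,
        params: AgentParams,
        n_mice: int,
        seed_seq: np.random.SeedSequence,
        cage_schedule: Optional[CageSchedule] = None,
        synchronized_sleep: bool = True,
    ) -> "CageAgents":
        """Build a cage with per-mouse RNGs split from one seed sequence.

        Child 0 of ``seed_seq`` drives the (shared) wake/sleep process,
        children 1..n drive the individual mice.
        """
        children = seed_seq.spawn(n_mice + 1)
        wake_rng = np.random.default_rng(children[0])
        shared = (
            WakeSleepProcess(params, wake_rng, cage_schedule) if synchronized_sleep else None
        )
        mice = []
        for i in range(n_mice):
            rng = np.random.default_rng(children[i + 1])
            wake = shared if shared is not None else WakeSleepProcess(params, rng, cage_schedule)
            mice.append(VirtualMouse(params, i, rng, wake=wake, cage_schedule=cage_schedule))
        return cls(mice)

    def spontaneous_licks(self, t0: float, t1: float) -> List[Tuple[float, int]]:
        out: List[Tuple[float, int]] = []
        for m in self.mice:
            out.extend((t, m.mouse_id) for t in m.spontaneous_licks(t0, t1))
        out.sort()
        return out

    def trial_licks(self, spec) -> List[Tuple[float, int]]:
        """Impulsive and tone-evoked licks for one trial, mice in id order."""
        out: List[Tuple[float, int]] = []
        for m in self.mice:
            t = m.early_lick(spec)
            if t is not None:
                out.append((t, m.mouse_id))
            if not spec.is_catch:
                t = m.tone_response(spec)
                if t is not None:
                    out.append((t, m.mouse_id))
        out.sort()
        return out

    def update_learning(self, day_index: int) -> None:
        for m in self.mice:
            m.update_learning(day_index)

    def adapt_to_delay(self, delay: float) -> None:
        for m in self.mice:
            m.adapt_to_delay(delay)

    def mouse(self, mouse_id: int) -> VirtualMouse:
        return self.mice[mouse_id]

    def first_awake(self, t: float) -> Optional[VirtualMouse]:
        for m in self.mice:
            if m.wake.awake_at(t):
                return m
        return None
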