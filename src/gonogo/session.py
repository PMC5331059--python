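"""Multi-day, multi-cage cohort simulation.

Ties the scheduler, virtual mice and trial engine together the way a
training run unfolds in the animal facility: every cage runs its six
staggered 60 min sessions per day; at the end of each day the daily peak
first-lick latency decides whether the response delay advances one step;
free water (10% of shaping trials) is removed once the first delay is
introduced; and a cage graduates from shaping to the operant task (short
tone, 2 s window, 1/3 catch trials) after holding the maximum delay for
two full days.  Agents update their learning state and adapt their lick
timing once per day.

Seeding: a master seed feeds one ``numpy.random.SeedSequence``; child ``i``
belongs to cage ``i`` and is split again into the engine RNG (child 0) and
the cage's agents (child 1, further split into wake process + one stream
per mouse).  Everything downstream is consumed in a fixed order, so a
master seed reproduces a cohort byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import stats
from .agent import CageAgents
from .config import ProtocolConfig
from .engine import maybe_advance_delay, run_session
from .events import write_events
from .schedule import active_block_starts

MINUTE = 60.0

#: consecutive days a cage must hold the maximum delay before the operant task
DAYS_AT_MAX_BEFORE_OPERANT = 2


@dataclass
class _CageState:
    cage_id: int
    agents: CageAgents
    rng: np.random.Generator
    phase: str = "shaping"
    delay: float = 0.0
    days_at_max: int = 0
    trial_counter: int = 0
    day_log: List[dict] = field(default_factory=list)


@dataclass
class CohortResult:
    """All trials plus per-cage and cage-averaged learning curves."""

    trials: pd.DataFrame
    curves: Dict[int, pd.DataFrame]
    cohort_curve: pd.DataFrame
    day_log: pd.DataFrame
    protocol: ProtocolConfig
    master_seed: int
    event_files: List[str] = field(default_factory=list)


def simulate_cohort(
    protocol: ProtocolConfig,
    days: int = 15,
    master_seed: int = 0,
    out_dir=None,
    start_phase: Optional[str] = None,
) -> CohortResult:
    """Simulate ``days`` of training for every cage in the schedule.

    ``start_phase`` defaults to the protocol's phase.  When ``out_dir`` is
    given, one JSONL event file per cage per day is written there.
    """
    schedule = protocol.cage_schedule
    start_phase = start_phase or protocol.phase
    root = np.random.SeedSequence(master_seed)
    cage_seqs = root.spawn(schedule.n_cages)
    cages: List[_CageState] = []
    for c, seq in enumerate(cage_seqs):
        eng_ss, agent_ss = seq.spawn(2)
        agents = CageAgents.from_params(
            protocol.agent, protocol.mice_per_cage, agent_ss, cage_schedule=schedule
        )
        cages.append(_CageState(
            cage_id=c, agents=agents, rng=np.random.default_rng(eng_ss),
            phase=start_phase,
        ))

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    event_files: List[str] = []
    all_trials: List[dict] = []

    for day in range(days):
        for cage in cages:
            day_trials: List[dict] = []
            day_events = [] if out_path is not None else None
            if cage.phase == "habituation":
                blocks = [(day * 86400.0, 86400.0)]
            else:
                blocks = [
                    (t0, schedule.active_block * MINUTE)
                    for t0 in active_block_starts(schedule, cage.cage_id, day)
                ]
            for t0, dur in blocks:
                det_cfg = _effective_detection(protocol, cage)
                res = run_session(
                    protocol, cage.agents, rng=cage.rng, cage_id=cage.cage_id,
                    t_start=t0, duration=dur, day_index=day, phase=cage.phase,
                    delay=cage.delay if cage.phase != "habituation" else None,
                    detection_config=det_cfg,
                    trial_id_start=cage.trial_counter,
                )
                cage.trial_counter = res.state.trial_counter
                day_trials.extend(res.trials)
                if day_events is not None:
                    day_events.extend(res.events)
            if out_path is not None:
                fname = out_path / f"cage{cage.cage_id}_day{day:02d}.jsonl"
                write_events(day_events, fname)
                event_files.append(str(fname))
            all_trials.extend(day_trials)
            _end_of_day_update(protocol, cage, day, day_trials)

    trials = pd.DataFrame(all_trials)
    curves = {}
    for cage in cages:
        sub = trials[trials["cage_id"] == cage.cage_id] if len(trials) else trials
        curves[cage.cage_id] = (
            stats.learning_curve(sub) if len(sub) else pd.DataFrame()
        )
    cohort_curve = average_curves(list(curves.values()))
    day_log = pd.DataFrame([r for cage in cages for r in cage.day_log])
    return CohortResult(
        trials=trials, curves=curves, cohort_curve=cohort_curve,
        day_log=day_log, protocol=protocol, master_seed=master_seed,
        event_files=event_files,
    )


def _effective_detection(protocol: ProtocolConfig, cage: _CageState):
    """Phase parameters as trained: free water is dropped once delays begin."""
    if cage.phase == "habituation":
        return None
    cfg = protocol.detection(cage.phase)
    update = {"response_delay": cage.delay}
    if cage.phase == "shaping" and cage.delay > 0:
        update["free_water_fraction"] = 0.0
    return cfg.model_copy(update=update)


def _end_of_day_update(protocol: ProtocolConfig, cage: _CageState, day: int,
                       day_trials: List[dict]) -> None:
    df = pd.DataFrame(day_trials)
    peak = None
    if len(df) and df["first_lick_latency"].notna().any():
        try:
            peak = stats.first_lick_stats(df).peak
        except ValueError:
            peak = None
    cage.day_log.append({
        "cage_id": cage.cage_id, "day_index": day, "phase": cage.phase,
        "delay": cage.delay, "n_trials": len(df),
        "peak_latency": peak if peak is not None else float("nan"),
    })
    if cage.phase == "habituation":
        cage.agents.update_learning(day + 1)
        return
    schedule = protocol.delay_schedule
    new_delay = maybe_advance_delay(
        peak, protocol.detection(cage.phase), cage.delay, schedule
    )
    cage.agents.adapt_to_delay(cage.delay)
    if cage.phase == "shaping":
        if cage.delay >= schedule.max_delay:
            cage.days_at_max += 1
            if cage.days_at_max >= DAYS_AT_MAX_BEFORE_OPERANT:
                cage.phase = "operant"
    cage.delay = new_delay
    cage.agents.update_learning(day + 1)


def average_curves(curves: List[pd.DataFrame]) -> pd.DataFrame:
    """Across-cage mean learning curve, indexed by day.

    Cages may sit at different delays on the same day; the mean delay is
    reported, matching how group learning curves are usually plotted.
    """
    frames = [c for c in curves if len(c)]
    if not frames:
        return pd.DataFrame()
    allc = pd.concat(frames, ignore_index=True)
    return (
        allc.groupby("day_index")
        .mean(numeric_only=True)
        .reset_index()
        .sort_values("day_index")
        .reset_index(drop=True)
    )
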