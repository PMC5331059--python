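"""Shared fixtures: agents, sessions, and an independent inverse-CDF oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gonogo import AgentParams, CageAgents, ProtocolConfig

#: a mouse that never licks, never sleeps and never detects anything
NULL_AGENT = dict(
    baseline_lick_rate=0.0,
    p_detect_initial=0.0,
    p_detect_final=0.0,
    impulsivity_initial=0.0,
    impulsivity_final=0.0,
    sleep_bout_rate=0.0,
    drink_lick_rate=0.0,
    habituation_drink_prob=0.0,
)


def make_cage(seed=0, n_mice=1, schedule=None, **overrides) -> CageAgents:
    params = AgentParams(**overrides)
    return CageAgents.from_params(params, n_mice, np.random.SeedSequence(seed),
                                  cage_schedule=schedule)


@pytest.fixture
def protocol() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture
def null_cage() -> CageAgents:
    return make_cage(**NULL_AGENT)


def z_bisect(p: float, tol: float = 1e-9) -> float:
    """Standard-normal inverse CDF by bisection on the CDF (independent oracle)."""
    from scipy.stats import norm

    lo, hi = -10.0, 10.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if norm.cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def dprime_bisect(h: float, f: float) -> float:
    return z_bisect(h) - z_bisect(f)


def make_trials(outcomes, cage_id=0, day_index=0, **extra) -> pd.DataFrame:
    """Minimal trial table from a list of outcome labels."""
    rows = []
    for i, label in enumerate(outcomes):
        is_catch = label in ("FALSE_ALARM", "CORRECT_REJECTION", "EARLY_CATCH")
        rows.append({
            "cage_id": cage_id, "trial_id": i, "day_index": day_index,
            "phase": "operant", "t_start": 12.0 * i, "is_catch": is_catch,
            "free_water": False, "delay": 0.75,
            "tone_onset": 12.0 * i + 0.5, "early_end": 12.0 * i + 1.25,
            "response_end": 12.0 * i + 3.25, "outcome": label,
            "first_lick_latency": extra.get("latency"),
            "rewarded": label == "HIT", "timeout_applied": label.startswith("EARLY"),
            "n_licks": 0, "lick_times": (),
        })
    df = pd.DataFrame(rows)
    for k, v in extra.items():
        if k != "latency":
            df[k] = v
    return df
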