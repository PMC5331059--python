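"""Trial engine: ITIs, quiet-period gating, trial geometry, contingencies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gonogo import (
    DetectionPhaseConfig,
    ProtocolConfig,
    build_trial,
    classify_trial,
    enforce_quiet_period,
    maybe_advance_delay,
    sample_iti,
)
from gonogo.engine import EngineState, TrialSpec


def _rng(seed=0):
    return np.random.default_rng(seed)


# -- sample_iti --------------------------------------------------------------


@pytest.mark.parametrize(
    "cfg_kind,pending,lo,hi",
    [
        ("shaping", 0, 5.0, 9.0),
        ("habituation", 0, 30.0, 300.0),
        ("shaping", 1, 25.0, 29.0),   # one 20 s time-out added
        ("shaping", 3, 65.0, 69.0),   # time-outs accumulate additively
    ],
)
def test_iti_ranges(cfg_kind, pending, lo, hi):
    p = ProtocolConfig()
    cfg = p.habituation if cfg_kind == "habituation" else p.shaping
    rng = _rng(1)
    draws = [sample_iti(cfg, pending, rng) for _ in range(500)]
    assert all(lo <= d <= hi for d in draws)
    assert max(draws) - min(draws) > 0.5 * (hi - lo)  # actually spread out


def test_iti_degenerate_range():
    cfg = DetectionPhaseConfig(iti_range=(7.0, 7.0))
    rng = _rng(0)
    assert sample_iti(cfg, 0, rng) == pytest.approx(7.0)
    assert sample_iti(cfg, 2, rng) == pytest.approx(47.0)


# -- enforce_quiet_period ----------------------------------------------------


def test_quiet_period_no_licks():
    assert enforce_quiet_period(102.0, [], 5.0) == 102.0


def test_quiet_period_single_recent_lick():
    assert enforce_quiet_period(102.0, [100.0], 5.0) == 105.0


def test_quiet_period_walks_the_lick_stream():
    # 100 blocks 101 -> 105; 103 blocks 105 -> 108; 106 blocks 108 -> 111
    assert enforce_quiet_period(101.0, [100.0, 103.0, 106.0], 5.0) == 111.0


def test_quiet_period_ignores_old_and_future_licks():
    assert enforce_quiet_period(102.0, [90.0, 96.9, 102.0, 200.0], 5.0) == 102.0


def test_quiet_period_deferred_beyond_horizon():
    assert enforce_quiet_period(101.0, [100.0], 5.0, horizon=103.0) is None


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=200, allow_nan=False), max_size=30),
    st.floats(min_value=0, max_value=200, allow_nan=False),
    st.floats(min_value=0.5, max_value=10, allow_nan=False),
)
def test_quiet_period_contract(licks, candidate, quiet):
    """Result is >= candidate, quiet-clean, and minimal (candidate or lick+q)."""
    licks = sorted(licks)
    t = enforce_quiet_period(candidate, licks, quiet)
    assert t >= candidate
    # open quiet window; 1e-9 absorbs float error of recomputing t - quiet
    assert not any(t - quiet + 1e-9 < l < t for l in licks)
    assert t == candidate or any(t == l + quiet for l in licks)


# -- build_trial -------------------------------------------------------------


def _state(delay, clock=100.0, phase="shaping"):
    return EngineState(phase=phase, current_delay=delay, clock=clock)


def test_build_trial_shaping_delay_zero():
    spec = build_trial(_state(0.0), ProtocolConfig().shaping, _rng(0))
    assert spec.tone_onset == 100.5
    assert spec.early_window == (100.0, 100.5)
    assert spec.response_window == (100.5, 103.5)  # 3 s from tone onset
    assert spec.tone_offset == 101.5


def test_build_trial_shaping_max_delay():
    cfg = ProtocolConfig().shaping
    spec = build_trial(_state(0.75), cfg, _rng(0))
    assert spec.response_window == (101.25, 104.25)
    assert spec.early_window == (100.0, 101.25)


def test_build_trial_operant_geometry_and_catch_rate():
    cfg = ProtocolConfig().operant
    rng = _rng(3)
    n_catch = 0
    n = 3000
    for i in range(n):
        spec = build_trial(_state(0.75, clock=i * 12.0, phase="operant"), cfg, rng)
        assert spec.tone_offset - spec.tone_onset == pytest.approx(0.5)
        assert spec.response_end - spec.early_end == pytest.approx(2.0)
        n_catch += spec.is_catch
        if spec.is_catch:
            assert not spec.free_water
    p = 1 / 3
    half = 2.576 * (p * (1 - p) / n) ** 0.5
    assert abs(n_catch / n - p) < half


def test_catch_trials_share_window_geometry():
    cfg = ProtocolConfig().operant
    rng = _rng(0)
    specs = [build_trial(_state(0.75, clock=0.0, phase="operant"), cfg, rng)
             for _ in range(50)]
    tone = next(s for s in specs if not s.is_catch)
    catch = next(s for s in specs if s.is_catch)
    assert (tone.early_window, tone.response_window) == (
        catch.early_window, catch.response_window
    )


# -- classify_trial ----------------------------------------------------------


def _spec(is_catch=False, free_water=False):
    # early window [0, 1.25), response window [1.25, 3.25)
    return TrialSpec(
        trial_id=0, t_start=0.0, is_catch=is_catch, free_water=free_water,
        delay=0.75, tone_onset=0.5, tone_offset=1.0, early_end=1.25,
        response_end=3.25,
    )


@pytest.mark.parametrize(
    "is_catch,licks,label,rewarded,timeout",
    [
        (False, [1.8], "HIT", True, False),
        (False, [0.9], "EARLY", False, True),
        (False, [0.9, 1.8], "EARLY", False, True),  # outcome fixed by first lick
        (False, [], "MISS", False, False),
        (False, [3.5], "MISS", False, False),       # lick after the window
        (True, [], "CORRECT_REJECTION", False, False),
        (True, [2.0], "FALSE_ALARM", False, False),
        (True, [0.4], "EARLY_CATCH", False, True),
    ],
)
def test_outcome_contingencies(is_catch, licks, label, rewarded, timeout):
    out = classify_trial(_spec(is_catch=is_catch), licks)
    assert out.label == label
    assert out.rewarded == rewarded
    assert out.timeout_applied == timeout
    if licks:
        assert out.first_lick_latency == pytest.approx(licks[0])
    else:
        assert out.first_lick_latency is None


def test_free_water_trial_is_rewarded_even_without_licks():
    out = classify_trial(_spec(free_water=True), [])
    assert out.label == "MISS" and out.rewarded


def test_unsorted_licks_rejected():
    with pytest.raises(ValueError):
        classify_trial(_spec(), [2.0, 1.0])
    with pytest.raises(ValueError):
        classify_trial(_spec(), [-0.5, 1.0])


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.booleans(),
    st.lists(st.floats(min_value=0, max_value=4, allow_nan=False), max_size=8),
)
def test_labels_partition_by_trial_type(is_catch, licks):
    out = classify_trial(_spec(is_catch=is_catch), sorted(licks))
    tone_labels = {"HIT", "MISS", "EARLY"}
    catch_labels = {"FALSE_ALARM", "CORRECT_REJECTION", "EARLY_CATCH"}
    assert out.label in (catch_labels if is_catch else tone_labels)
    assert out.timeout_applied == (out.label in ("EARLY", "EARLY_CATCH"))


# -- maybe_advance_delay -----------------------------------------------------


def test_delay_advances_when_peak_shifts_into_window(protocol):
    cfg, sched = protocol.shaping, protocol.delay_schedule
    # delay 0.25: window spans [0.75, 3.75) relative to trial start
    assert maybe_advance_delay(1.0, cfg, 0.25, sched) == 0.5
    assert maybe_advance_delay(0.5, cfg, 0.25, sched) == 0.25  # peak still early
    assert maybe_advance_delay(4.0, cfg, 0.25, sched) == 0.25  # past the window
    assert maybe_advance_delay(None, cfg, 0.25, sched) == 0.25


def test_delay_never_exceeds_maximum(protocol):
    cfg, sched = protocol.shaping, protocol.delay_schedule
    assert maybe_advance_delay(2.0, cfg, 0.75, sched) == 0.75
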