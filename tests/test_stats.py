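"""Behavioral statistics: rates, d', latencies, lick traces, correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gonogo import (
    compute_dprime,
    compute_rates,
    correlate,
    first_lick_stats,
    learning_curve,
    lick_rate_trace,
    rate_summary,
)

from conftest import dprime_bisect, make_trials

# final-session per-cage group statistics reported for the four-cage cohort
FOUR_CAGE_RATES = pd.DataFrame({
    "cage_id": [0, 1, 2, 3],
    "hit_rate": [4.1, 6.4, 5.0, 5.2],      # percent
    "early_rate": [1.8, 3.0, 1.1, 0.9],    # percent of all trials
    "fa_rate": [0.5, 0.7, 0.2, 0.3],       # percent
    "dprime": [1.1, 0.87, 0.9, 1.3],
})


# -- rates -------------------------------------------------------------------

def test_rates_direct_counting():
    outcomes = ["HIT"] * 6 + ["MISS"] * 52 + ["EARLY"] * 2 + ["CORRECT_REJECTION"] * 30
    s = compute_rates(make_trials(outcomes))
    assert (s.n_tone, s.n_catch, s.n_trials) == (60, 30, 90)
    assert s.hit_rate == pytest.approx(0.10)
    assert s.fa_rate == 0.0
    assert s.early_rate == pytest.approx(2 / 90)
    assert s.denominator_convention == "per_type"


def test_rates_per_total_convention():
    outcomes = ["HIT"] * 6 + ["MISS"] * 52 + ["EARLY"] * 2 + ["CORRECT_REJECTION"] * 30
    s = compute_rates(make_trials(outcomes), convention="per_total")
    assert s.hit_rate == pytest.approx(6 / 90)
    assert s.fa_rate == 0.0


def test_all_withheld_gives_zero_rates():
    s = compute_rates(make_trials(["MISS"] * 10 + ["CORRECT_REJECTION"] * 5))
    assert (s.hit_rate, s.fa_rate, s.early_rate) == (0.0, 0.0, 0.0)
    assert math.isfinite(s.dprime)  # extreme rates corrected, not infinite


def test_no_catch_trials_flagged():
    with pytest.warns(UserWarning, match="catch"):
        s = compute_rates(make_trials(["HIT", "MISS"]))
    assert math.isnan(s.fa_rate) and math.isnan(s.dprime)


def test_four_cage_summary_hit_early_ratio():
    out = rate_summary(FOUR_CAGE_RATES)
    assert out["hit_early_ratio"] == pytest.approx(3.044, abs=1e-3)
    assert out["mean_dprime"] == pytest.approx(1.0425, abs=1e-4)


# -- d' ----------------------------------------------------------------------

def test_dprime_symmetry_point():
    assert compute_dprime(0.5, 0.5) == pytest.approx(0.0, abs=1e-12)


def test_dprime_unit_normal_points():
    # Phi(1) and Phi(-1): Z-transforms are exactly +-1
    assert compute_dprime(0.841345, 0.158655) == pytest.approx(2.0, abs=1e-4)


def test_dprime_low_rate_example_matches_oracle():
    want = dprime_bisect(0.041, 0.005)
    assert want == pytest.approx(0.837, abs=1e-3)
    assert compute_dprime(0.041, 0.005) == pytest.approx(want, abs=1e-6)


def test_extreme_rate_correction_rule():
    # 0 -> 1/(2n), 1 -> 1 - 1/(2n) of the relevant trial count
    want = dprime_bisect(1 - 1 / 40, 1 / 60)
    assert compute_dprime(1.0, 0.0, n_tone=20, n_catch=30) == pytest.approx(
        want, abs=1e-6
    )
    with pytest.raises(ValueError):
        compute_dprime(0.0, 0.1)  # correction impossible without a count
    with pytest.raises(ValueError):
        compute_dprime(1.2, 0.1)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.floats(min_value=0.001, max_value=0.999),
    st.floats(min_value=0.001, max_value=0.999),
)
def test_dprime_antisymmetry_and_oracle(h, f):
    d = compute_dprime(h, f)
    assert d == pytest.approx(-compute_dprime(f, h), abs=1e-9)
    assert d == pytest.approx(dprime_bisect(h, f), abs=1e-6)


def test_dprime_monotone_in_hit_rate():
    grid = np.linspace(0.01, 0.99, 25)
    d = [compute_dprime(h, 0.2) for h in grid]
    assert all(b > a for a, b in zip(d, d[1:]))


# -- first-lick latency ------------------------------------------------------

def test_latency_median_simple():
    df = make_trials(["HIT"] * 3)
    df["first_lick_latency"] = [1.0, 2.0, 3.0]
    fls = first_lick_stats(df)
    assert fls.median == 2.0


def test_single_latency_is_its_own_peak():
    df = make_trials(["HIT"])
    df["first_lick_latency"] = [1.7]
    fls = first_lick_stats(df)
    assert fls.median == fls.peak == 1.7


def test_peak_is_modal_histogram_bin_midpoint():
    # 40 latencies inside [1.6, 1.7), 60 scattered one per other bin
    scattered = [0.05 + 0.1 * k for k in range(70) if k != 16][:60]
    values = [1.63] * 20 + [1.68] * 20 + scattered
    df = make_trials(["HIT"] * len(values))
    df["first_lick_latency"] = values
    fls = first_lick_stats(df, bin_width=0.1)
    assert fls.peak == pytest.approx(1.65)


def test_no_licks_flagged():
    df = make_trials(["MISS"] * 5)
    with pytest.raises(ValueError, match="no trials with licks"):
        first_lick_stats(df)


# -- lick-rate trace ---------------------------------------------------------

def _trace_trials(lick_lists):
    df = make_trials(["MISS"] * len(lick_lists))
    df["lick_times"] = [tuple(l) for l in lick_lists]
    return df


def test_trace_all_zero_without_licks():
    tr = lick_rate_trace(_trace_trials([[], [], []]), trial_filter=None)
    assert np.all(tr.p_lick == 0.0)
    assert tr.n_trials == 3


def test_trace_certain_bin():
    tr = lick_rate_trace(_trace_trials([[1.02], [1.07]]), trial_filter=None)
    k = int(1.0 / 0.1)
    assert tr.p_lick[k] == 1.0
    assert tr.p_lick.sum() == pytest.approx(1.0)  # only that bin is hit


def test_trace_direct_average_and_order_invariance():
    lists = [[1.02], [], [], []]
    tr = lick_rate_trace(_trace_trials(lists), trial_filter=None)
    assert tr.p_lick[10] == pytest.approx(0.25)
    shuffled = lick_rate_trace(_trace_trials(lists[::-1]), trial_filter=None)
    assert np.array_equal(tr.p_lick, shuffled.p_lick)


def test_trace_multiple_licks_one_bin_count_once():
    tr = lick_rate_trace(_trace_trials([[1.01, 1.04, 1.09]]), trial_filter=None)
    assert tr.p_lick[10] == 1.0
    assert tr.p_lick.sum() == 1.0


def test_trace_rejects_bad_bins_and_mixed_durations():
    with pytest.raises(ValueError):
        lick_rate_trace(_trace_trials([[1.0]]), bin_width=0.0, trial_filter=None)
    df = _trace_trials([[1.0], [1.0]])
    df.loc[1, "response_end"] = df.loc[1, "t_start"] + 5.0
    with pytest.raises(ValueError, match="mixed durations"):
        lick_rate_trace(df, trial_filter=None)


# -- learning curves and correlations ---------------------------------------

def _curve(x, y):
    return pd.DataFrame({"delay": x, "peak_latency": y})


def test_affine_relation_gives_unit_correlation():
    x = [0.0, 0.25, 0.5, 0.75]
    r, p = correlate(_curve(x, [xi + 0.5 for xi in x]), "delay", "peak_latency")
    assert r == pytest.approx(1.0)
    r, _ = correlate(_curve(x, [-xi for xi in x]), "delay", "peak_latency")
    assert r == pytest.approx(-1.0)


def test_correlation_hand_computed_case():
    x = np.array([0.0, 0.25, 0.5, 0.75])
    y = np.array([0.3, 0.6, 0.5, 0.9])
    # independent oracle: textbook Pearson formula
    want = float(np.sum((x - x.mean()) * (y - y.mean()))
                 / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    assert want == pytest.approx(0.8779, abs=1e-4)
    r, p = correlate(_curve(x, y), "delay", "peak_latency")
    assert r == pytest.approx(want, abs=1e-12)
    assert 0.0 < p < 1.0


def test_correlation_needs_three_days_and_variation():
    with pytest.raises(ValueError):
        correlate(_curve([0.0, 0.25], [1.0, 2.0]), "delay", "peak_latency")
    with pytest.warns(UserWarning, match="constant"):
        r, p = correlate(_curve([0.5] * 4, [1, 2, 3, 4]), "delay", "peak_latency")
    assert math.isnan(r) and math.isnan(p)


def test_learning_curve_aggregates_per_day():
    frames = []
    for day, (delay, lat) in enumerate([(0.0, 0.8), (0.25, 1.0), (0.5, 1.3)]):
        df = make_trials(["HIT"] * 4 + ["MISS"] * 4 + ["EARLY"] * 2,
                         day_index=day)
        df["delay"] = delay
        df["first_lick_latency"] = [lat] * 10
        frames.append(df)
    curve = learning_curve(pd.concat(frames, ignore_index=True))
    assert list(curve["day_index"]) == [0, 1, 2]
    assert list(curve["delay"]) == [0.0, 0.25, 0.5]
    assert list(curve["peak_latency"]) == [0.8, 1.0, 1.3]
    assert curve["hit_rate"].iloc[0] == pytest.approx(0.4)
    assert curve["early_rate"].iloc[0] == pytest.approx(0.2)
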