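"""Behavioral statistics: outcome rates, d', latencies, lick rates, learning.

Definitions
-----------
Hits and false alarms are trials whose only pre-window history is quiet and
whose first rewarded-window lick follows a tone (HIT) or a silent catch
trial (FALSE_ALARM).  Early responses are trials whose first lick fell in
the early window.  Sensitivity is ``d' = Z(hit rate) - Z(false-alarm
rate)`` with ``Z`` the standard-normal inverse CDF; rates of exactly 0 or 1
are replaced by ``1/(2n)`` and ``1 - 1/(2n)`` of the relevant trial count
before inversion (the standard correction).

Two denominator conventions are supported, because printed group statistics
in the field are often ambiguous between them:

* ``per_type`` (default, standard signal detection): hit rate over tone
  trials, false-alarm rate over catch trials, early rate over all trials;
* ``per_total``: every numerator divided by the total trial count.

First-lick latency is the time of the first lick from trial onset; its
distribution peak is the midpoint of the modal histogram bin (0.1 s bins by
default).  The lick-rate trace is the probability of at least one lick per
time bin, averaged across trials (a lick PSTH on a 0/1 indicator).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import (
    CATCH_LABELS,
    CORRECT_REJECTION,
    EARLY,
    EARLY_CATCH,
    FALSE_ALARM,
    HIT,
    MISS,
    TONE_LABELS,
)

DETECTION_LABELS = set(TONE_LABELS) | set(CATCH_LABELS)


@dataclass
class SessionSummary:
    n_trials: int
    n_tone: int
    n_catch: int
    hit_rate: float
    fa_rate: float
    early_rate: float
    dprime: float
    median_first_lick_latency: float
    peak_first_lick_latency: float
    denominator_convention: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FirstLickStats:
    latencies: np.ndarray
    median: float
    peak: float
    bin_width: float


@dataclass
class LickRateTrace:
    bin_edges: np.ndarray
    p_lick: np.ndarray
    n_trials: int
    trial_filter: Optional[str]


def _detection_trials(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["outcome"].isin(DETECTION_LABELS)]


def compute_rates(trials: pd.DataFrame, convention: str = "per_type") -> SessionSummary:
    """Outcome rates (and d', when catch trials exist) for a trial table."""
    if convention not in ("per_type", "per_total"):
        raise ValueError(f"unknown denominator convention {convention!r}")
    det = _detection_trials(trials)
    if len(det) == 0:
        raise ValueError("no detection trials in table")
    counts = det["outcome"].value_counts()
    n_tone = int(counts.reindex(TONE_LABELS, fill_value=0).sum())
    n_catch = int(counts.reindex(CATCH_LABELS, fill_value=0).sum())
    n_total = n_tone + n_catch
    n_hit = int(counts.get(HIT, 0))
    n_fa = int(counts.get(FALSE_ALARM, 0))
    n_early = int(counts.get(EARLY, 0)) + int(counts.get(EARLY_CATCH, 0))

    if convention == "per_type":
        hit_rate = n_hit / n_tone if n_tone else float("nan")
        fa_rate = n_fa / n_catch if n_catch else float("nan")
    else:
        hit_rate = n_hit / n_total
        fa_rate = n_fa / n_total
    early_rate = n_early / n_total

    if n_tone and n_catch:
        dprime = compute_dprime(hit_rate, fa_rate, n_tone=n_tone, n_catch=n_catch)
    else:
        dprime = float("nan")
        if not n_catch:
            warnings.warn("no catch trials: false-alarm rate and d' undefined",
                          stacklevel=2)

    fls = first_lick_stats(det) if det["first_lick_latency"].notna().any() else None
    return SessionSummary(
        n_trials=n_total,
        n_tone=n_tone,
        n_catch=n_catch,
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        early_rate=early_rate,
        dprime=dprime,
        median_first_lick_latency=fls.median if fls else float("nan"),
        peak_first_lick_latency=fls.peak if fls else float("nan"),
        denominator_convention=convention,
    )


def compute_dprime(
    hit_rate: float, fa_rate: float, n_tone: int = 0, n_catch: int = 0
) -> float:
    """``Z(hit) - Z(fa)`` with the 1/(2n) correction for extreme rates."""
    for name, r in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    h = _clip_rate(hit_rate, n_tone, "n_tone")
    f = _clip_rate(fa_rate, n_catch, "n_catch")
    return float(sps.norm.ppf(h) - sps.norm.ppf(f))


def _clip_rate(r: float, n: int, name: str) -> float:
    if r in (0.0, 1.0):
        if n <= 0:
            raise ValueError(f"{name} required to correct a rate of exactly {r}")
        eps = 1.0 / (2.0 * n)
        return eps if r == 0.0 else 1.0 - eps
    return r


def first_lick_stats(
    trials: pd.DataFrame, bin_width: float = 0.1, tone_only: bool = False
) -> FirstLickStats:
    """First-lick latencies with their median and histogram-mode peak.

    The peak is the midpoint of the modal ``bin_width`` bin (bins anchored
    at 0); ties resolve to the earliest bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    df = trials
    if tone_only:
        df = df[~df["is_catch"].astype(bool)]
    lat = pd.to_numeric(df["first_lick_latency"], errors="coerce").dropna().to_numpy()
    if lat.size == 0:
        raise ValueError("no trials with licks: latency statistics undefined")
    median = float(np.median(lat))
    if lat.min() == lat.max():  # point mass: the mode is the value itself
        return FirstLickStats(latencies=lat, median=median, peak=float(lat[0]),
                              bin_width=bin_width)
    n_bins = max(1, int(math.floor(lat.max() / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(lat, bins=edges)
    k = int(np.argmax(counts))
    peak = float((edges[k] + edges[k + 1]) / 2.0)
    return FirstLickStats(latencies=lat, median=median, peak=peak, bin_width=bin_width)


def lick_rate_trace(
    trials: pd.DataFrame,
    bin_width: float = 0.1,
    trial_filter: Optional[str] = "tone",
    t_max: Optional[float] = None,
) -> LickRateTrace:
    """Probability of >= 1 lick per time bin, averaged across trials.

    ``trial_filter`` selects ``"tone"`` or ``"catch"`` trials (``None`` for
    all).  Trials must share one duration unless ``t_max`` is given.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    df = _detection_trials(trials)
    if trial_filter == "tone":
        df = df[~df["is_catch"].astype(bool)]
    elif trial_filter == "catch":
        df = df[df["is_catch"].astype(bool)]
    elif trial_filter is not None:
        raise ValueError(f"unknown trial_filter {trial_filter!r}")
    if len(df) == 0:
        raise ValueError("no trials to average")
    if t_max is None:
        durations = np.round(df["response_end"].to_numpy() - df["t_start"].to_numpy(), 3)
        uniq = np.unique(durations)
        if uniq.size != 1:
            raise ValueError(
                "trials have mixed durations; pass t_max explicitly"
            )
        t_max = float(uniq[0])
    n_bins = max(1, int(round(t_max / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    acc = np.zeros(n_bins)
    for ts in df["lick_times"]:
        if ts:
            counts, _ = np.histogram(np.asarray(ts), bins=edges)
            acc += counts > 0
    return LickRateTrace(
        bin_edges=edges,
        p_lick=acc / len(df),
        n_trials=len(df),
        trial_filter=trial_filter,
    )


def learning_curve(trials: pd.DataFrame, bin_width: float = 0.1) -> pd.DataFrame:
    """Per-day peak/median latency, required delay and outcome rates.

    One row per training day; days without any lick have NaN latencies and
    days without catch trials have NaN false-alarm rate and d'.
    """
    if "day_index" not in trials.columns:
        raise ValueError("trial table needs a day_index column")
    rows = []
    for day, df in trials.groupby("day_index"):
        det = _detection_trials(df)
        if len(det) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = compute_rates(det)
        try:
            fls = first_lick_stats(det, bin_width=bin_width)
            peak, med = fls.peak, fls.median
        except ValueError:
            peak, med = float("nan"), float("nan")
        rows.append({
            "day_index": int(day),
            "delay": float(np.nanmedian(det["delay"].to_numpy(dtype=float))),
            "peak_latency": peak,
            "median_latency": med,
            "hit_rate": summ.hit_rate,
            "early_rate": summ.early_rate,
            "fa_rate": summ.fa_rate,
            "dprime": summ.dprime,
            "n_trials": summ.n_trials,
        })
    return pd.DataFrame(rows).sort_values("day_index").reset_index(drop=True)


def correlate(curve: pd.DataFrame, x_field: str, y_field: str) -> Tuple[float, float]:
    """Pearson r and two-sided p between two learning-curve columns.

    NaN rows are dropped; needs >= 3 complete days; a constant series
    yields ``(nan, nan)`` with a warning.
    """
    x = pd.to_numeric(curve[x_field], errors="coerce")
    y = pd.to_numeric(curve[y_field], errors="coerce")
    mask = x.notna() & y.notna()
    x, y = x[mask].to_numpy(), y[mask].to_numpy()
    if x.size < 3:
        raise ValueError("need at least 3 days for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: correlation undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    r, p = sps.pearsonr(x, y)
    return (float(r), float(p))


def rate_summary(per_cage: pd.DataFrame) -> dict:
    """Group-level summary of a per-cage rate table.

    Expects columns ``hit_rate`` and ``early_rate`` (any consistent unit)
    and optionally ``fa_rate`` and ``dprime``.  Returns the across-cage
    means plus the mean(hit)/mean(early) ratio.
    """
    out = {
        "n_cages": int(len(per_cage)),
        "mean_hit_rate": float(per_cage["hit_rate"].mean()),
        "mean_early_rate": float(per_cage["early_rate"].mean()),
    }
    out["hit_early_ratio"] = (
        out["mean_hit_rate"] / out["mean_early_rate"]
        if out["mean_early_rate"] else float("nan")
    )
    if "fa_rate" in per_cage:
        out["mean_fa_rate"] = float(per_cage["fa_rate"].mean())
    if "dprime" in per_cage:
        out["mean_dprime"] = float(per_cage["dprime"].mean())
    return out


def habituation_lick_fraction(trials: pd.DataFrame) -> float:
    """Fraction of habituation trials with at least one lick."""
    hab = trials[trials["phase"] == "habituation"]
    if len(hab) == 0:
        raise ValueError("no habituation trials")
    return float((hab["outcome"] == "LICKED").mean())
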