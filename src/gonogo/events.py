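"""On-disk event format and the event-stream -> trial-table transformation.

Event logs are JSON Lines: a header record carrying the schema version,
then one JSON object per behavioral event in non-decreasing time order with
a stable field order (``t, cage_id, mouse_id, event_type, trial_id,
payload``).  Times are seconds on the session clock at fixed 1 ms
resolution (lick sensors operate at millisecond scale).  ``mouse_id`` is
optional: files without it emulate rigs whose lick sensor cannot tell
cagemates apart, while the simulator keeps ground-truth identity.

The per-trial summary table is exported as flat CSV for spreadsheet users;
lick times within a trial are semicolon-joined seconds relative to trial
start.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace
from typing import Iterable, List, Optional

import pandas as pd

SCHEMA_VERSION = 1
_HEADER = {
    "record": "header",
    "format": "gonogo-events",
    "schema_version": SCHEMA_VERSION,
    "time_resolution_s": 0.001,
}

EVENT_TYPES = frozenset({
    "SESSION_START", "PHASE_CHANGE", "CAGE_ACTIVE", "CAGE_INACTIVE",
    "TRIAL_START", "TONE_ON", "TONE_OFF", "LICK",
    "REWARD_ON", "REWARD_OFF", "TIMEOUT_START", "TRIAL_END",
})

TRIAL_COLUMNS = [
    "cage_id", "trial_id", "day_index", "phase", "t_start", "is_catch",
    "free_water", "delay", "tone_onset", "early_end", "response_end",
    "outcome", "first_lick_latency", "rewarded", "timeout_applied",
    "n_licks", "lick_times",
]


class EventLogError(ValueError):
    """Malformed event stream or file."""


@dataclass
class EventRecord:
    """A single timestamped behavioral event."""

    t: float
    cage_id: int
    event_type: str
    mouse_id: Optional[int] = None
    trial_id: Optional[int] = None
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "t": self.t,
                "cage_id": self.cage_id,
                "mouse_id": self.mouse_id,
                "event_type": self.event_type,
                "trial_id": self.trial_id,
                "payload": self.payload,
            },
            separators=(",", ":"),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "EventRecord":
        if d.get("event_type") not in EVENT_TYPES:
            raise EventLogError(f"unknown event_type {d.get('event_type')!r}")
        return cls(
            t=float(d["t"]),
            cage_id=int(d["cage_id"]),
            event_type=d["event_type"],
            mouse_id=d.get("mouse_id"),
            trial_id=d.get("trial_id"),
            payload=d.get("payload") or {},
        )


def write_events(events: Iterable[EventRecord], path) -> None:
    """Write a header plus one JSON line per event (lossless round trip)."""
    prev = -math.inf
    with open(path, "w") as fh:
        fh.write(json.dumps(_HEADER, separators=(",", ":")) + "\n")
        for e in events:
            if e.t < prev:
                raise EventLogError(f"timestamp regression at t={e.t}")
            prev = e.t
            fh.write(e.to_json() + "\n")


def read_events(path) -> List[EventRecord]:
    """Read and validate an event file.

    Raises :class:`EventLogError` with a line number on malformed lines,
    on schema-version mismatch and on timestamp regressions.
    """
    path = Path(path)
    events: List[EventRecord] = []
    prev = -math.inf
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise EventLogError(f"{path.name} line {lineno}: bad JSON ({exc})") from exc
            if lineno == 1:
                if d.get("record") != "header" or d.get("format") != _HEADER["format"]:
                    raise EventLogError(f"{path.name} line 1: missing event-log header")
                if d.get("schema_version") != SCHEMA_VERSION:
                    raise EventLogError(
                        f"{path.name}: schema version {d.get('schema_version')} "
                        f"not supported (expected {SCHEMA_VERSION})"
                    )
                continue
            try:
                e = EventRecord.from_dict(d)
            except (KeyError, TypeError, ValueError) as exc:
                raise EventLogError(f"{path.name} line {lineno}: {exc}") from exc
            if e.t < prev:
                raise EventLogError(
                    f"{path.name} line {lineno}: timestamp regression ({e.t} < {prev})"
                )
            prev = e.t
            events.append(e)
    return events


def events_to_trials(events: Iterable[EventRecord], check: bool = True) -> pd.DataFrame:
    """One row per TRIAL_START/TRIAL_END pair, licks assigned by timestamp.

    Streams may interleave cages; trials are paired per ``cage_id``.  When
    ``check`` is true the outcome is recomputed from the licks and compared
    against the logged payload; a mismatch raises :class:`EventLogError`.
    """
    from .engine import classify_trial  # local import to avoid a cycle

    open_trials: dict = {}
    rows: List[dict] = []
    for e in events:
        if e.event_type == "TRIAL_START":
            if e.cage_id in open_trials:
                raise EventLogError(
                    f"TRIAL_START for cage {e.cage_id} while trial "
                    f"{open_trials[e.cage_id]['trial_id']} is open"
                )
            open_trials[e.cage_id] = {
                "trial_id": e.trial_id,
                "t_start": e.t,
                "payload": e.payload,
                "licks": [],
            }
        elif e.event_type == "LICK":
            tr = open_trials.get(e.cage_id)
            if tr is not None and e.trial_id == tr["trial_id"]:
                tr["licks"].append((e.t, e.mouse_id))
        elif e.event_type == "TRIAL_END":
            tr = open_trials.pop(e.cage_id, None)
            if tr is None or e.trial_id != tr["trial_id"]:
                raise EventLogError(
                    f"unpaired TRIAL_END (cage {e.cage_id}, trial {e.trial_id})"
                )
            rows.append(_finalize_trial(e, tr, check, classify_trial))
    if open_trials:
        ids = {c: tr["trial_id"] for c, tr in open_trials.items()}
        raise EventLogError(f"unpaired TRIAL_START records: {ids}")
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df


def _finalize_trial(end_event, tr, check, classify_trial) -> dict:
    sp = tr["payload"]
    ep = end_event.payload
    t0 = tr["t_start"]
    lick_abs = [t for t, _ in tr["licks"]]
    phase = sp.get("phase", "shaping")
    row = {
        "cage_id": end_event.cage_id,
        "trial_id": tr["trial_id"],
        "day_index": sp.get("day_index", 0),
        "phase": phase,
        "t_start": t0,
        "is_catch": bool(sp.get("is_catch", False)),
        "free_water": bool(sp.get("free_water", phase == "habituation")),
        "delay": sp.get("delay", float("nan")),
        "tone_onset": sp.get("tone_onset", float("nan")),
        "early_end": sp.get("early_end", float("nan")),
        "response_end": sp.get("response_end", end_event.t),
        "outcome": ep.get("outcome"),
        "first_lick_latency": ep.get("first_lick_latency"),
        "rewarded": bool(ep.get("rewarded", False)),
        "timeout_applied": bool(ep.get("timeout_applied", False)),
        "n_licks": len(tr["licks"]),
        "lick_times": tuple(round(t - t0, 3) for t in lick_abs),
    }
    if check:
        if phase == "habituation":
            dur = sp.get("trial_duration")
            licked = any(t0 <= t < t0 + dur for t in lick_abs) if dur else bool(lick_abs)
            expect = "LICKED" if licked else "NO_LICK"
            if ep.get("outcome") != expect:
                raise EventLogError(
                    f"trial {tr['trial_id']}: logged outcome {ep.get('outcome')} "
                    f"but licks imply {expect}"
                )
        else:
            spec = SimpleNamespace(
                t_start=t0,
                is_catch=row["is_catch"],
                free_water=row["free_water"],
                delay=row["delay"],
                tone_onset=row["tone_onset"],
                early_end=row["early_end"],
                response_end=row["response_end"],
            )
            out = classify_trial(spec, lick_abs)
            mismatches = []
            if out.label != ep.get("outcome"):
                mismatches.append(f"outcome {ep.get('outcome')} != {out.label}")
            if bool(ep.get("rewarded")) != out.rewarded:
                mismatches.append("rewarded flag")
            if bool(ep.get("timeout_applied")) != out.timeout_applied:
                mismatches.append("timeout flag")
            lat = ep.get("first_lick_latency")
            if (lat is None) != (out.first_lick_latency is None) or (
                lat is not None and abs(lat - out.first_lick_latency) > 1e-9
            ):
                mismatches.append("first_lick_latency")
            if mismatches:
                raise EventLogError(
                    f"trial {tr['trial_id']} inconsistent with its licks: "
                    + "; ".join(mismatches)
                )
    return row


# -- trial-table CSV ---------------------------------------------------------


def trials_to_csv(trials: pd.DataFrame, path) -> None:
    df = trials.copy()
    df["lick_times"] = df["lick_times"].map(
        lambda ts: ";".join(f"{t:.3f}" for t in ts)
    )
    df.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    def _parse(s):
        if isinstance(s, str) and s:
            return tuple(float(x) for x in s.split(";"))
        return ()
    df["lick_times"] = df["lick_times"].map(_parse)
    df["first_lick_latency"] = pd.to_numeric(df["first_lick_latency"], errors="coerce")
    return df
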