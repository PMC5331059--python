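"""Typed, validated protocol configuration with the training paradigm defaults.

The training protocol has three explicit phases:

* ``habituation`` -- water flows freely for the first 10 s of each 20 s
  trial (ITI 30-300 s, 90 min on / 90 min off blocks) so mice learn to use
  the waterspout;
* ``shaping`` -- 0.5 s pre-stimulus silence, a 1 s tone (6 kHz label, 60 dB
  SPL label), a 3 s response window, ITIs of 5-9 s, a 5 s pre-trial quiet
  period, 2 s water rewards, free water on 10% of trials, a 20 s time-out
  for premature licks, and a response delay stepped through 0, 0.25, 0.5,
  0.75 s as the animals' lick timing shifts with the window;
* ``operant`` -- the tone shrinks to 0.5 s, the response window to 2 s, free
  water is removed and a third of trials are silent catch trials used to
  estimate false alarms.

Tone frequency/level are metadata labels only; no audio is synthesised.
Configs are read and written as a small versioned YAML dialect; unspecified
fields take the defaults above.  A commented example ships in
``examples/protocol.yaml``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator

from .agent import AgentParams
from .schedule import CageSchedule

CONFIG_VERSION = 1


class HabituationConfig(BaseModel):
    """Waterspout-habituation phase parameters (seconds unless noted)."""

    trial_duration: float = Field(default=20.0, gt=0.0)
    water_on_duration: float = Field(default=10.0, ge=0.0)
    iti_range: Tuple[float, float] = (30.0, 300.0)
    on_block: float = Field(default=90.0, gt=0.0)   # minutes
    off_block: float = Field(default=90.0, gt=0.0)  # minutes

    @model_validator(mode="after")
    def _check(self) -> "HabituationConfig":
        if self.water_on_duration > self.trial_duration:
            raise ValueError("water_on_duration must not exceed trial_duration")
        lo, hi = self.iti_range
        if not (0 < lo <= hi):
            raise ValueError("iti_range must satisfy 0 < min <= max")
        return self


class DelaySchedule(BaseModel):
    """Ordered response-delay steps; the last step is the maximum delay."""

    steps: list[float] = Field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75])
    max_delay: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DelaySchedule":
        if not self.steps:
            raise ValueError("delay schedule needs at least one step")
        if self.steps[0] < 0:
            raise ValueError("delays must be non-negative")
        if any(b <= a for a, b in zip(self.steps, self.steps[1:])):
            raise ValueError("delay steps must be strictly increasing")
        if self.max_delay is None:
            self.max_delay = self.steps[-1]
        elif self.max_delay != self.steps[-1]:
            raise ValueError("max_delay must equal the last delay step")
        return self

    def next_step(self, current: float) -> float:
        """The step after ``current`` (capped at the maximum)."""
        for s in self.steps:
            if s > current:
                return s
        return self.steps[-1]


class DetectionPhaseConfig(BaseModel):
    """Parameters of a tone-detection phase (shaping or operant).

    Class defaults are the shaping values; use :meth:`operant` for the
    final-task values (0.5 s tone, 2 s window, 1/3 catch trials, no free
    water).
    """

    pre_stim_silence: float = Field(default=0.5, ge=0.0)
    tone_duration: float = Field(default=1.0, ge=0.0)
    tone_freq: float = Field(default=6000.0, gt=0.0)   # Hz, label only
    tone_level: float = Field(default=60.0)            # dB SPL, label only
    response_window_duration: float = Field(default=3.0, ge=0.0)
    response_delay: float = Field(default=0.0, ge=0.0)
    iti_range: Tuple[float, float] = (5.0, 9.0)
    quiet_period: float = Field(default=5.0, ge=0.0)
    reward_duration: float = Field(default=2.0, ge=0.0)
    free_water_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    free_water_duration: float = Field(default=0.5, ge=0.0)
    timeout_duration: float = Field(default=20.0, ge=0.0)
    catch_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)

    @model_validator(mode="after")
    def _check(self) -> "DetectionPhaseConfig":
        lo, hi = self.iti_range
        if not (0 < lo <= hi):
            raise ValueError("iti_range must satisfy 0 < min <= max")
        return self

    @classmethod
    def shaping(cls, **overrides) -> "DetectionPhaseConfig":
        return cls(**overrides)

    @classmethod
    def operant(cls, **overrides) -> "DetectionPhaseConfig":
        defaults = dict(
            tone_duration=0.5,
            response_window_duration=2.0,
            response_delay=0.75,
            free_water_fraction=0.0,
            catch_fraction=1.0 / 3.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


Phase = Literal["habituation", "shaping", "operant"]


class ProtocolConfig(BaseModel):
    """Everything needed to reproduce a training run."""

    version: int = CONFIG_VERSION
    phase: Phase = "shaping"
    mice_per_cage: int = Field(default=3, ge=1)
    habituation: HabituationConfig = Field(default_factory=HabituationConfig)
    shaping: DetectionPhaseConfig = Field(default_factory=DetectionPhaseConfig.shaping)
    operant: DetectionPhaseConfig = Field(default_factory=DetectionPhaseConfig.operant)
    delay_schedule: DelaySchedule = Field(default_factory=DelaySchedule)
    cage_schedule: CageSchedule = Field(default_factory=CageSchedule)
    agent: AgentParams = Field(default_factory=AgentParams)

    @model_validator(mode="after")
    def _check(self) -> "ProtocolConfig":
        if self.version != CONFIG_VERSION:
            raise ValueError(
                f"unsupported config version {self.version} (expected {CONFIG_VERSION})"
            )
        return self

    def detection(self, phase: Optional[str] = None) -> DetectionPhaseConfig:
        """The detection-phase parameters for ``phase`` (default: current)."""
        phase = phase or self.phase
        if phase == "shaping":
            return self.shaping
        if phase == "operant":
            return self.operant
        raise ValueError(f"phase {phase!r} has no detection parameters")


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed or validated."""


def parse_config(text: str) -> ProtocolConfig:
    """Parse YAML text into a validated :class:`ProtocolConfig`.

    An empty document yields the full protocol defaults.
    """
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return ProtocolConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError names field + constraint
        raise ConfigError(str(exc)) from exc


def load_config(path) -> ProtocolConfig:
    """Load and validate a protocol config file."""
    return parse_config(Path(path).read_text())


def dump_config(config: ProtocolConfig) -> str:
    """Serialize a config to YAML that :func:`parse_config` reparses equal."""
    return yaml.safe_dump(config.model_dump(), sort_keys=False)


def save_config(config: ProtocolConfig, path) -> None:
    Path(path).write_text(dump_config(config))
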