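"""Agent state containers: prey (pigeon-oid) and predator (pred-oid)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ManoeuvreStatus", "PigeonState", "PredatorState", "PHASES"]

PHASES = ("pursuit", "attack", "retreat")


@dataclass
class ManoeuvreStatus:
    """An active discrete escape manoeuvre.

    The total turning angle and duration are drawn once, independently,
    from two gamma distributions; the turn is then executed at the
    constant signed rate ``turn_rate = total_angle_signed / duration``.
    """

    remaining_duration: float   # s, counts down to 0
    turn_rate: float            # deg/s, signed (+ = left)
    total_angle: float          # deg, unsigned sampled magnitude
    sampled_duration: float     # s, sampled magnitude

    def __post_init__(self) -> None:
        if self.total_angle <= 0 or self.sampled_duration <= 0:
            raise ValueError("manoeuvre angle and duration must be positive")
        if not 0.0 < self.remaining_duration <= self.sampled_duration + 1e-9:
            raise ValueError("remaining_duration out of range")
        expected = self.total_angle / self.sampled_duration
        if abs(abs(self.turn_rate) - expected) > 1e-6 * max(1.0, expected):
            raise ValueError("|turn_rate| must equal total_angle / sampled_duration")


@dataclass
class PigeonState:
    """One prey agent.

    ``cruise_speed`` and ``escape_tendency`` are individual-specific,
    drawn once per run.  ``reaction_clock`` is the time left until this
    agent next refreshes its perception of neighbours and predator.
    """

    id: int
    position: np.ndarray        # (2,), m
    heading: float              # deg CCW from +x, in [0, 360)
    speed: float                # m/s, > 0
    cruise_speed: float         # m/s
    escape_tendency: float      # in [0, 1], probability scale per perception update
    reaction_clock: float = 0.0
    manoeuvre: Optional[ManoeuvreStatus] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.speed <= 0 or self.cruise_speed <= 0:
            raise ValueError("speed and cruise_speed must be positive")
        if not 0.0 <= self.escape_tendency <= 1.0:
            raise ValueError("escape_tendency must be in [0, 1]")
        self.heading = float(self.heading) % 360.0

    @property
    def is_manoeuvring(self) -> bool:
        return self.manoeuvre is not None


@dataclass
class PredatorState:
    """The pred-oid: kinematics plus hunting-cycle phase and timer.

    The phase cycles pursuit -> attack -> retreat; phase durations sum
    to the configured cycle duration.
    """

    position: np.ndarray = field(default_factory=lambda: np.zeros(2))
    heading: float = 0.0
    speed: float = 20.0
    phase: str = "pursuit"
    phase_clock: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        self.heading = float(self.heading) % 360.0
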