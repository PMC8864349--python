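"""Synthetic GPS-like track fixtures with known ground truth.

Generates kinematically consistent 2-D tracks (default 5 Hz, metres)
of small flocks realizing scripted scenarios — straight flight,
constant-rate arcs, scripted turn sequences, solitary and sub-flock
departures, and whole-flock turns — together with the exact list of
turn segments and split events the detectors are expected to recover.
Ground-truth split events are stated for the default 10 m / 2 s rule;
turn labels for the default 10 deg/s straight threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .detect import SplitEvent, TurnSegment

__all__ = ["FixtureSpec", "GroundTruth", "make_fixture", "SCENARIOS"]

SCENARIOS = ("straight", "arc", "scripted_turns", "solitary_split",
             "subflock_split", "follow_all")

_SPACING = 2.0        # m, formation spacing
_SPEED = 18.0         # m/s, fixture flight speed
_STRAIGHT_THRESHOLD = 10.0
_SPLIT_DISTANCE = 10.0
_SPLIT_MIN_DURATION = 2.0


@dataclass(frozen=True)
class FixtureSpec:
    """A scripted track scenario.

    ``params`` carries the scenario-specific knobs: ``rate_deg_s``
    (arc), ``pieces`` as (angle_deg, duration_s) tuples with angle 0
    meaning straight (scripted_turns), ``departure_time`` and
    ``bearing_deg`` (splits), ``size`` (subflock_split), ``turn_time``
    / ``angle_deg`` / ``turn_duration`` (follow_all).
    """

    scenario: str
    n_agents: int = 10
    duration_s: float = 60.0
    sampling_hz: float = 5.0
    noise_sd_m: float = 0.0
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_agents < 1 or self.duration_s <= 0 or self.sampling_hz <= 0:
            raise ValueError("n_agents, duration_s and sampling_hz must be positive")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be >= 0")
        if self.scenario == "subflock_split":
            k = self.params.get("size", 2)
            if not 1 <= k < self.n_agents - k:
                raise ValueError("sub-flock must be smaller than the remaining flock")


@dataclass
class GroundTruth:
    """Events the detectors must recover from the fixture at zero noise."""

    turn_segments: list[TurnSegment] = field(default_factory=list)
    split_events: list[SplitEvent] = field(default_factory=list)


def _rate_schedule(spec: FixtureSpec) -> list[tuple[float, float]]:
    """(duration, turn rate deg/s) pieces covering the whole flight."""
    p = spec.params
    if spec.scenario == "straight":
        return [(spec.duration_s, 0.0)]
    if spec.scenario == "arc":
        return [(spec.duration_s, float(p.get("rate_deg_s", 12.0)))]
    if spec.scenario == "scripted_turns":
        pieces = [(float(d), (float(a) / float(d)) if a else 0.0)
                  for a, d in p["pieces"]]
        used = sum(d for d, _ in pieces)
        if used < spec.duration_s:
            pieces.append((spec.duration_s - used, 0.0))
        return pieces
    if spec.scenario == "follow_all":
        t0 = float(p.get("turn_time", spec.duration_s / 3))
        angle = float(p.get("angle_deg", 60.0))
        dur = float(p.get("turn_duration", 2.0))
        return [(t0, 0.0), (dur, angle / dur),
                (max(spec.duration_s - t0 - dur, 0.0), 0.0)]
    raise ValueError(spec.scenario)


def _turn_ground_truth(schedule: list[tuple[float, float]]) -> list[TurnSegment]:
    segments = []
    t = 0.0
    for dur, rate in schedule:
        if dur <= 0:
            continue
        cum = rate * dur
        ang_vel = abs(rate)
        label = "straight" if ang_vel < _STRAIGHT_THRESHOLD else "turn"
        segments.append(TurnSegment(t, t + dur, cum, ang_vel, label))
        t += dur
    # merge adjacent same-label straight pieces (the detector cannot
    # distinguish two consecutive straights)
    merged: list[TurnSegment] = []
    for seg in segments:
        if (merged and merged[-1].label == "straight" == seg.label):
            prev = merged.pop()
            cum = prev.cum_angle + seg.cum_angle
            dur = seg.t_end - prev.t_start
            merged.append(TurnSegment(prev.t_start, seg.t_end, cum,
                                      abs(cum) / dur, "straight"))
        else:
            merged.append(seg)
    return merged


def _formation(n: int) -> np.ndarray:
    """Column formation: agent i at (0, i * spacing)."""
    return np.column_stack([np.zeros(n), _SPACING * np.arange(n)])


def _integrate_common(spec: FixtureSpec, times: np.ndarray) -> np.ndarray:
    """Positions (T, A, 2) when all agents share one heading schedule."""
    schedule = _rate_schedule(spec)
    fine_dt = 0.002
    n_fine = int(round(spec.duration_s / fine_dt)) + 1
    heading = np.zeros(n_fine)
    t_edges = np.cumsum([0.0] + [d for d, _ in schedule])
    tt = np.arange(n_fine) * fine_dt
    rate = np.zeros(n_fine)
    for (dur, r), a, b in zip(schedule, t_edges[:-1], t_edges[1:]):
        rate[(tt >= a - 1e-12) & (tt < b - 1e-12)] = r
    heading = np.cumsum(rate) * fine_dt
    heading = np.r_[0.0, heading[:-1]]
    hu = np.column_stack([np.cos(np.radians(heading)), np.sin(np.radians(heading))])
    path = np.cumsum(hu * _SPEED * fine_dt, axis=0)
    path = np.vstack([[0.0, 0.0], path[:-1]])
    idx = np.clip(np.round(times / fine_dt).astype(int), 0, n_fine - 1)
    base = _formation(spec.n_agents)
    return path[idx][:, None, :] + base[None, :, :]


def _split_positions(spec: FixtureSpec, times: np.ndarray,
                     departers: list[int]) -> np.ndarray:
    """Piecewise-linear paths: departers change heading at departure_time."""
    t_d = float(spec.params.get("departure_time", 10.0))
    bearing = float(spec.params.get("bearing_deg", 25.0))
    base = _formation(spec.n_agents)
    v_main = np.array([_SPEED, 0.0])
    v_dep = _SPEED * np.array([np.cos(np.radians(bearing)),
                               np.sin(np.radians(bearing))])
    pos = np.empty((len(times), spec.n_agents, 2))
    for a in range(spec.n_agents):
        before = np.minimum(times, t_d)
        after = np.maximum(times - t_d, 0.0)
        v2 = v_dep if a in departers else v_main
        pos[:, a] = base[a] + before[:, None] * v_main + after[:, None] * v2
    return pos


def _split_ground_truth(pos: np.ndarray, times: np.ndarray,
                        departers: list[int]) -> list[SplitEvent]:
    """Split event computed directly from the generated positions,
    independent of the detector: the departing group is split from the
    moment its closest member is more than the split distance from
    every remaining bird (the last link to the main flock breaks),
    provided the excursion lasts the minimum split duration."""
    rest = [a for a in range(pos.shape[1]) if a not in departers]
    gap = np.linalg.norm(pos[:, departers, None, :] - pos[:, None, rest, :],
                         axis=-1).min(axis=(1, 2))
    flagged = np.flatnonzero(gap > _SPLIT_DISTANCE)
    if flagged.size == 0:
        return []
    i0 = int(flagged[0])
    run_end = i0
    while run_end + 1 < len(gap) and gap[run_end + 1] > _SPLIT_DISTANCE:
        run_end += 1
    if times[run_end] - times[i0] < _SPLIT_MIN_DURATION:
        return []
    return [SplitEvent(t_start=float(times[i0]), member_ids=frozenset(departers),
                       size=len(departers),
                       kind="solitary" if len(departers) == 1 else "sub-flock",
                       merged_back_at=None)]


def make_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the fixture's track table and its ground-truth events."""
    n_samples = int(round(spec.duration_s * spec.sampling_hz))
    times = np.arange(n_samples) / spec.sampling_hz
    truth = GroundTruth()

    if spec.scenario in ("straight", "arc", "scripted_turns", "follow_all"):
        pos = _integrate_common(spec, times)
        truth.turn_segments = _turn_ground_truth(_rate_schedule(spec))
    else:
        if spec.scenario == "solitary_split":
            departers = [spec.n_agents - 1]
        else:
            departers = list(range(spec.n_agents - spec.params.get("size", 2),
                                   spec.n_agents))
        # split scenarios define split ground truth only: the departure
        # kinks the centroid trajectory, so its turn content is not scripted
        pos = _split_positions(spec, times, departers)
        truth.split_events = _split_ground_truth(pos, times, departers)

    if spec.noise_sd_m > 0:
        rng = np.random.default_rng(spec.seed)
        pos = pos + rng.normal(0.0, spec.noise_sd_m, pos.shape)

    n = spec.n_agents
    tracks = pd.DataFrame({
        "t_s": np.repeat(times, n),
        "agent_id": np.tile(np.arange(n), n_samples),
        "x_m": pos[:, :, 0].ravel(),
        "y_m": pos[:, :, 1].ravel(),
        "is_predator": 0,
    })
    return tracks, truth
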