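"""Run one hunting cycle and collect its tracks and manoeuvre records.

A cycle is a fixed-length flight (one full predator hunting cycle, 60 s
by default) of a freshly initialized flock, with or without the
predator.  Tracks are written at the configured output rate (5 Hz by
default), mirroring the structure of GPS logger data; every discrete
escape manoeuvre is logged with its initiator, onset time, sampled
angle and duration, and distance to the predator at onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .agents import PredatorState
from .config import SimConfig
from .flock import Flock, step
from .predation import spawn_predator, update_predator

__all__ = ["SimResult", "simulate_cycle", "TRACK_COLUMNS", "MANOEUVRE_COLUMNS"]

TRACK_COLUMNS = ["t_s", "agent_id", "x_m", "y_m", "heading_deg", "speed_ms",
                 "is_predator", "manoeuvring"]
MANOEUVRE_COLUMNS = ["cycle_id", "initiator_id", "t_start_s", "total_angle_deg",
                     "duration_s", "ang_vel_deg_s", "dist_to_pred_m"]

PREDATOR_ID = -1


@dataclass
class SimResult:
    """Tracks (tidy time x agent table) and manoeuvre log of one cycle."""

    tracks: pd.DataFrame
    manoeuvres: pd.DataFrame
    cfg: SimConfig
    cycle_id: int = 0


def _rng_streams(seed) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent init and escape-sampling streams from one seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_ss, escape_ss = ss.spawn(2)
    return np.random.default_rng(init_ss), np.random.default_rng(escape_ss)


def simulate_cycle(cfg: SimConfig,
                   seed: Union[int, np.random.SeedSequence, None] = None,
                   predator_enabled: bool = True,
                   cycle_id: int = 0,
                   duration: Optional[float] = None) -> SimResult:
    """Simulate one cycle and return its tracks and manoeuvre records.

    ``seed`` overrides ``cfg.seed``; initialization and escape sampling
    use independent sub-streams, so identical seeds give bit-identical
    output.  With ``predator_enabled=False`` the flight is a control:
    no predator rows, no avoidance force and no manoeuvres.
    """
    if seed is None:
        seed = cfg.seed
    init_rng, escape_rng = _rng_streams(seed)
    flock = Flock.init_random(cfg, init_rng)

    # settle the flock (predator-free, not recorded) before the cycle
    for _ in range(int(round(cfg.warmup_s / cfg.dt))):
        step(flock, None, cfg, escape_rng)

    predator: Optional[PredatorState] = (
        spawn_predator(flock, cfg) if predator_enabled else None
    )

    total = cfg.cycle_duration if duration is None else duration
    n_steps = int(round(total / cfg.dt))
    stride = cfg.output_stride
    n = len(flock)

    rows: list[np.ndarray] = []
    man_rows: list[tuple] = []

    def record(t: float) -> None:
        block = np.empty((n + (predator is not None), 8))
        block[:n, 0] = t
        block[:n, 1] = flock.ids
        block[:n, 2:4] = flock.pos
        block[:n, 4] = flock.heading
        block[:n, 5] = flock.speed
        block[:n, 6] = 0.0
        block[:n, 7] = flock.man_active
        if predator is not None:
            block[n] = [t, PREDATOR_ID, predator.position[0], predator.position[1],
                        predator.heading, predator.speed, 1.0, 0.0]
        rows.append(block)

    for k in range(n_steps):
        t = k * cfg.dt
        if k % stride == 0:
            record(t)
        step(flock, predator, cfg, escape_rng)
        for agent_id, man, dist in flock.started:
            man_rows.append((cycle_id, agent_id, t, man.total_angle,
                             man.sampled_duration, man.turn_rate, dist))
        if predator is not None:
            update_predator(predator, flock, cfg, cfg.dt)
    if n_steps % stride == 0:
        record(n_steps * cfg.dt)

    tracks = pd.DataFrame(np.concatenate(rows), columns=TRACK_COLUMNS)
    tracks["agent_id"] = tracks["agent_id"].astype(int)
    tracks["is_predator"] = tracks["is_predator"].astype(int)
    tracks["manoeuvring"] = tracks["manoeuvring"].astype(int)
    manoeuvres = pd.DataFrame(man_rows, columns=MANOEUVRE_COLUMNS)
    return SimResult(tracks=tracks, manoeuvres=manoeuvres, cfg=cfg, cycle_id=cycle_id)
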