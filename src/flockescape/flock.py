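"""Flock coordination, speed control and the time-stepping integrator.

Each pigeon-oid coordinates with up to its seven closest neighbours
(topological interaction) within a maximum interaction distance: it is
attracted toward their centre of mass, aligns with their mean heading,
and turns away from its single closest neighbour when that bird is
inside the separation radius.  Alignment is the strongest of the three
coordination forces.  Speed is regulated by a linear drag toward each
bird's individual cruise speed plus a bounded catch-up acceleration
when the neighbourhood's centre of mass lies ahead.

Steering forces act as lateral accelerations: a steering vector of
lateral magnitude ``a`` turns a bird flying at speed ``v`` at the
angular rate ``a / v`` (circular motion of radius ``v^2 / a``), capped
at a configurable maximum turn rate.  Perception is asynchronous: each
agent refreshes its steering only when its own reaction clock expires,
and the clocks are staggered across the flock.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .agents import ManoeuvreStatus, PigeonState, PredatorState
from .config import SimConfig
from .geometry import heading_unit, unit
from .predation import escape_probability, manoeuvre_sign

__all__ = [
    "Flock",
    "topological_neighbours",
    "coordination_force",
    "speed_control",
    "step",
]

_CATCHUP_SAT = 1.5   # m, longitudinal offset at which catch-up saturates
_DUE_TOL = 1e-9


# ---------------------------------------------------------------------------
# array-level primitives (single source of truth for the force arithmetic)

def _neighbour_order(i: int, pos: np.ndarray, ids: np.ndarray,
                     cfg: SimConfig) -> np.ndarray:
    """Indices of agent ``i``'s topological neighbours, nearest first.

    At most ``n_topological`` other agents within the maximum
    interaction distance; equal distances break toward the lower id.
    """
    d = np.linalg.norm(pos - pos[i], axis=1)
    d[i] = np.inf
    eligible = np.flatnonzero(d <= cfg.max_interaction_distance)
    if eligible.size == 0:
        return eligible
    order = eligible[np.lexsort((ids[eligible], d[eligible]))]
    return order[: cfg.n_topological]


def _coordination(i: int, pos: np.ndarray, heading: np.ndarray,
                  nb: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if nb.size == 0:
        return np.zeros(2)
    com = pos[nb].mean(axis=0)
    to_com = com - pos[i]
    d_com = np.linalg.norm(to_com)
    # attraction and separation taper linearly near equilibrium so that
    # birds at rest spacing feel no bang-bang impulses
    att = min(d_com / cfg.attraction_saturation, 1.0)
    force = cfg.weight_attraction * att * unit(to_com)
    force = force + cfg.weight_alignment * unit(heading_unit(heading[nb]).mean(axis=0))
    closest = nb[0]
    d_close = np.linalg.norm(pos[closest] - pos[i])
    if d_close < cfg.separation_radius:
        taper = 1.0 - d_close / cfg.separation_radius
        force = force + cfg.weight_separation * taper * unit(pos[i] - pos[closest])
    return force


def _speed_accel(i: int, pos: np.ndarray, head_unit: np.ndarray,
                 speed: np.ndarray, cruise: np.ndarray, nb: np.ndarray,
                 cfg: SimConfig) -> float:
    a = cfg.weight_cruise * (cruise[i] - speed[i])
    if nb.size:
        proj = float(np.dot(pos[nb].mean(axis=0) - pos[i], head_unit))
        a += cfg.weight_catchup * float(np.clip(proj / _CATCHUP_SAT, -1.0, 1.0))
    return float(a)


# ---------------------------------------------------------------------------
# array-backed flock container

class Flock:
    """Structure-of-arrays state of a simulated flock.

    ``started`` lists the manoeuvres begun in the most recent step as
    ``(agent_id, ManoeuvreStatus, distance_to_predator)`` tuples.
    """

    def __init__(self, ids, pos, heading, speed, cruise, tendency, clock):
        self.ids = np.asarray(ids, dtype=int)
        self.pos = np.asarray(pos, dtype=float)
        self.heading = np.asarray(heading, dtype=float) % 360.0
        self.speed = np.asarray(speed, dtype=float)
        self.cruise = np.asarray(cruise, dtype=float)
        self.tendency = np.asarray(tendency, dtype=float)
        self.clock = np.asarray(clock, dtype=float)
        n = len(self.ids)
        self.lat_acc = np.zeros(n)
        self.spd_acc = np.zeros(n)
        self.man_active = np.zeros(n, dtype=bool)
        self.man_remaining = np.zeros(n)
        self.man_rate = np.zeros(n)
        self.man_total = np.zeros(n)
        self.man_sampled = np.zeros(n)
        self.started: list[tuple[int, ManoeuvreStatus, float]] = []

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def init_random(cls, cfg: SimConfig, rng: np.random.Generator) -> "Flock":
        """Fresh flock: positions uniform in a disc, headings near +x,
        individual cruise speeds and escape tendencies drawn once, and
        reaction clocks staggered uniformly over one reaction interval."""
        n = cfg.n_pigeons
        radius = cfg.effective_init_radius * np.sqrt(rng.random(n))
        theta = rng.random(n) * 2.0 * np.pi
        pos = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        heading = rng.normal(0.0, cfg.heading_jitter_sd_deg, n)
        cruise = np.clip(rng.normal(cfg.cruise_speed_mean, cfg.cruise_speed_sd, n),
                         0.5 * cfg.cruise_speed_mean, 1.5 * cfg.cruise_speed_mean)
        tendency = rng.uniform(cfg.tendency_min, cfg.tendency_max, n)
        clock = rng.uniform(0.0, cfg.reaction_interval, n)
        return cls(np.arange(n), pos, heading, cruise.copy(), cruise, tendency, clock)

    @classmethod
    def from_states(cls, states: Sequence[PigeonState]) -> "Flock":
        f = cls(
            ids=[s.id for s in states],
            pos=[s.position for s in states],
            heading=[s.heading for s in states],
            speed=[s.speed for s in states],
            cruise=[s.cruise_speed for s in states],
            tendency=[s.escape_tendency for s in states],
            clock=[s.reaction_clock for s in states],
        )
        for k, s in enumerate(states):
            if s.manoeuvre is not None:
                m = s.manoeuvre
                f.man_active[k] = True
                f.man_remaining[k] = m.remaining_duration
                f.man_rate[k] = m.turn_rate
                f.man_total[k] = m.total_angle
                f.man_sampled[k] = m.sampled_duration
        return f

    def state(self, k: int) -> PigeonState:
        man = None
        if self.man_active[k]:
            man = ManoeuvreStatus(
                remaining_duration=float(self.man_remaining[k]),
                turn_rate=float(self.man_rate[k]),
                total_angle=float(self.man_total[k]),
                sampled_duration=float(self.man_sampled[k]),
            )
        return PigeonState(
            id=int(self.ids[k]),
            position=self.pos[k].copy(),
            heading=float(self.heading[k]),
            speed=float(self.speed[k]),
            cruise_speed=float(self.cruise[k]),
            escape_tendency=float(self.tendency[k]),
            reaction_clock=float(self.clock[k]),
            manoeuvre=man,
        )

    def states(self) -> list[PigeonState]:
        return [self.state(k) for k in range(len(self))]

    def centroid(self) -> np.ndarray:
        return self.pos.mean(axis=0)


# ---------------------------------------------------------------------------
# public per-agent operations

def _index_of(focal: PigeonState, states: Sequence[PigeonState]) -> int:
    for k, s in enumerate(states):
        if s is focal or s.id == focal.id:
            return k
    raise ValueError("focal agent not found in flock")


def topological_neighbours(focal: PigeonState, flock: Sequence[PigeonState],
                           cfg: SimConfig) -> list[PigeonState]:
    """Up to ``n_topological`` nearest other agents within the maximum
    interaction distance, ordered by distance (ties toward lower id).

    A flock of one bird has no neighbours; two distant sub-flocks see
    only their own members, so the effective neighbourhood shrinks.
    """
    states = list(flock)
    i = _index_of(focal, states)
    pos = np.array([s.position for s in states], dtype=float)
    ids = np.array([s.id for s in states], dtype=int)
    nb = _neighbour_order(i, pos, ids, cfg)
    return [states[j] for j in nb]


def coordination_force(focal: PigeonState, neighbours: Sequence[PigeonState],
                       cfg: SimConfig) -> np.ndarray:
    """Weighted sum of attraction, alignment and separation steering.

    Attraction points at the neighbours' centre of mass (full strength
    beyond the saturation distance, tapering linearly to zero at it),
    alignment along their mean heading, and separation away from the
    single closest neighbour, tapering to zero at the separation
    radius.  An empty neighbourhood yields the zero vector.
    """
    states = [focal, *neighbours]
    pos = np.array([s.position for s in states], dtype=float)
    heading = np.array([s.heading for s in states], dtype=float)
    if len(neighbours) == 0:
        return np.zeros(2)
    d = np.linalg.norm(pos[1:] - pos[0], axis=1)
    nb = 1 + np.argsort(d, kind="stable")
    return _coordination(0, pos, heading, nb, cfg)


def speed_control(focal: PigeonState, neighbours: Sequence[PigeonState],
                  cfg: SimConfig) -> float:
    """Scalar acceleration (m/s^2): linear drag toward the bird's own
    cruise speed plus a bounded catch-up term toward the neighbourhood
    centre of mass (accelerate when it lies ahead, brake when behind)."""
    states = [focal, *neighbours]
    pos = np.array([s.position for s in states], dtype=float)
    speed = np.array([s.speed for s in states], dtype=float)
    cruise = np.array([s.cruise_speed for s in states], dtype=float)
    nb = np.arange(1, len(states))
    return _speed_accel(0, pos, heading_unit(focal.heading), speed, cruise, nb, cfg)


# ---------------------------------------------------------------------------
# integrator

def step(flock, predator: Optional[PredatorState], cfg: SimConfig,
         rng: np.random.Generator):
    """Advance the flock by one integration step of ``cfg.dt`` seconds.

    Positions advance every step along the current heading; steering
    (coordination, continuous avoidance, escape-manoeuvre triggering)
    is refreshed per agent only when its reaction clock expires.
    Manoeuvring agents ignore neighbours and the avoidance force: they
    turn at their sampled rate and keep only the cruise-speed drag.

    Accepts either a :class:`Flock` (mutated in place and returned) or
    a sequence of :class:`PigeonState` (a new list is returned).
    """
    if not isinstance(flock, Flock):
        states = list(flock)
        if not states:
            raise ValueError("cannot step an empty flock")
        f = Flock.from_states(states)
        step(f, predator, cfg, rng)
        return f.states()

    f = flock
    n = len(f)
    if n == 0:
        raise ValueError("cannot step an empty flock")
    dt = cfg.dt
    f.started = []

    due = np.flatnonzero(f.clock <= _DUE_TOL)
    if due.size:
        # hot loop: scalar math mirrors coordination_force / speed_control
        # (equivalence is covered by a dedicated test)
        hu_all = heading_unit(f.heading)
        px, py = f.pos[:, 0], f.pos[:, 1]
        max_d2 = cfg.max_interaction_distance ** 2
        for i in due:
            if f.man_active[i]:
                continue
            dx = px - px[i]
            dy = py - py[i]
            d2 = dx * dx + dy * dy
            d2[i] = np.inf
            elig = np.flatnonzero(d2 <= max_d2)
            hx, hy = hu_all[i]
            lat = 0.0
            spd = cfg.weight_cruise * (f.cruise[i] - f.speed[i])
            if elig.size:
                de = np.sqrt(d2[elig])
                order = np.lexsort((f.ids[elig], de))
                nb = elig[order[: cfg.n_topological]]
                k = nb.size
                cx = px[nb].sum() / k - px[i]
                cy = py[nb].sum() / k - py[i]
                d_com = math.hypot(cx, cy)
                fx = fy = 0.0
                if d_com > 0.0:
                    att = cfg.weight_attraction * min(
                        d_com / cfg.attraction_saturation, 1.0) / d_com
                    fx += att * cx
                    fy += att * cy
                ax = hu_all[nb, 0].sum()
                ay = hu_all[nb, 1].sum()
                a_norm = math.hypot(ax, ay)
                if a_norm > 0.0:
                    fx += cfg.weight_alignment * ax / a_norm
                    fy += cfg.weight_alignment * ay / a_norm
                closest = nb[0]
                d_close = math.sqrt(d2[closest])
                if d_close < cfg.separation_radius:
                    taper = 1.0 - d_close / cfg.separation_radius
                    if d_close > 0.0:
                        sep = cfg.weight_separation * taper / d_close
                        fx -= sep * (px[closest] - px[i])
                        fy -= sep * (py[closest] - py[i])
                lat = hx * fy - hy * fx
                proj = cx * hx + cy * hy
                spd += cfg.weight_catchup * min(max(proj / _CATCHUP_SAT, -1.0), 1.0)
            if predator is not None:
                pdx = px[i] - predator.position[0]
                pdy = py[i] - predator.position[1]
                dist = math.hypot(pdx, pdy)
                if dist <= cfg.predator.influence_distance:
                    s = manoeuvre_sign(predator.position, predator.heading,
                                       f.pos[i], float(f.heading[i]))
                    decay = min(math.exp(-dist / cfg.escape_distance_scale),
                                cfg.avoidance_cap)
                    lat += s * cfg.weight_predator_avoidance * decay
                p = escape_probability(dist, float(f.tendency[i]), cfg)
                if p > 0.0 and rng.random() < p:
                    angle = max(float(rng.gamma(cfg.gamma_angle_shape,
                                                cfg.gamma_angle_scale)), 1e-6)
                    duration = max(float(rng.gamma(cfg.gamma_duration_shape,
                                                   cfg.gamma_duration_scale)), 1e-6)
                    sign = manoeuvre_sign(predator.position, predator.heading,
                                          f.pos[i], float(f.heading[i]))
                    f.man_active[i] = True
                    f.man_remaining[i] = duration
                    f.man_rate[i] = sign * angle / duration
                    f.man_total[i] = angle
                    f.man_sampled[i] = duration
                    f.started.append((int(f.ids[i]),
                                      ManoeuvreStatus(duration,
                                                      sign * angle / duration,
                                                      angle, duration),
                                      dist))
            f.lat_acc[i] = lat
            f.spd_acc[i] = spd
        f.clock[due] += cfg.reaction_interval

    man = f.man_active.copy()
    if man.any():
        f.heading[man] = (f.heading[man] + f.man_rate[man] * dt) % 360.0
        f.man_remaining[man] -= dt
        done = man & (f.man_remaining <= _DUE_TOL)
        if done.any():
            f.man_active[done] = False
            f.clock[done] = 0.0       # refresh perception right after finishing
            f.lat_acc[done] = 0.0
    coord = ~man
    if coord.any():
        omega = np.degrees(f.lat_acc[coord] / f.speed[coord])
        omega = np.clip(omega, -cfg.max_turn_rate_deg_s, cfg.max_turn_rate_deg_s)
        f.heading[coord] = (f.heading[coord] + omega * dt) % 360.0

    accel = np.where(man, cfg.weight_cruise * (f.cruise - f.speed), f.spd_acc)
    f.speed = np.clip(f.speed + accel * dt, cfg.min_speed, cfg.max_speed)
    f.pos = f.pos + (f.speed * dt)[:, None] * heading_unit(f.heading)
    f.clock -= dt
    return f
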