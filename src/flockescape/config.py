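"""Configuration objects for the simulator and the trajectory detectors.

All model and analysis parameters live here.  Empirically anchored
quantities (seven topological neighbours, the 60 s hunting cycle, 5 Hz
output sampling, the 10 deg/s straight-flight threshold and the
10 m / 2 s split rule) keep those values as defaults; every remaining
constant is a documented modelling assumption and can be overridden from
a flat key-value config file (see :func:`load_config`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = [
    "PredatorParams",
    "SimConfig",
    "DetectConfig",
    "ConfigError",
    "load_config",
    "config_to_dict",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised when a configuration file or value is invalid."""


@dataclass(frozen=True)
class PredatorParams:
    """Parameters of the pred-oid's three-phase hunting cycle.

    The predator follows the flock at ``pursuit_distance`` (pursuit),
    accelerates towards its closest prey (attack), then leaves until it
    is ``retreat_distance`` away (retreat).  ``phase_fractions`` divide
    the cycle duration between the three phases, in that order.
    """

    pursuit_distance: float = 30.0
    retreat_distance: float = 300.0
    pursuit_speed: float = 20.0
    attack_speed: float = 35.0
    retreat_speed: float = 25.0
    phase_fractions: tuple[float, float, float] = (0.5, 0.17, 0.33)
    turn_rate_limit_deg_s: float = 120.0
    influence_distance: float = 300.0   # avoidance force zero beyond this
    weave_amplitude: float = 25.0       # m, lateral wander of the pursuit aim
    weave_period: float = 6.0           # s, period of the pursuit weave
    station_gain: float = 0.5           # 1/s, speed response to range error

    def __post_init__(self) -> None:
        if not self.attack_speed > self.pursuit_speed:
            raise ConfigError("attack_speed must exceed pursuit_speed")
        f = self.phase_fractions
        if len(f) != 3 or any(not 0.0 < x < 1.0 for x in f):
            raise ConfigError("phase_fractions must be three values in (0, 1)")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ConfigError("phase_fractions must sum to 1")
        for name in ("pursuit_distance", "retreat_distance", "pursuit_speed",
                     "retreat_speed", "turn_rate_limit_deg_s", "influence_distance",
                     "weave_period", "station_gain"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.weave_amplitude < 0:
            raise ConfigError("weave_amplitude must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """All parameters of one simulated flock-plus-predator run.

    Coordinates are planar Cartesian metres; headings are degrees
    counter-clockwise from +x, and positive angular velocity is a left
    turn.  Coordination force weights are lateral accelerations in
    m/s^2 applied at full (unit-vector) strength; alignment must be the
    strongest of the three coordination forces.
    """

    n_pigeons: int = 10
    dt: float = 0.05                      # s, integration step
    reaction_interval: float = 0.1        # s, perception-update period
    n_topological: int = 7
    max_interaction_distance: float = 50.0  # m
    separation_radius: float = 3.0          # m
    attraction_saturation: float = 12.0     # m, attraction at full strength beyond

    weight_alignment: float = 18.0
    weight_attraction: float = 14.0
    weight_separation: float = 9.0
    weight_cruise: float = 2.0            # 1/s, linear drag toward cruise speed
    weight_catchup: float = 5.0           # m/s^2, saturated catch-up acceleration
    weight_predator_avoidance: float = 12.0
    avoidance_cap: float = 0.35           # close-range saturation of the decay factor

    max_turn_rate_deg_s: float = 300.0    # cap on steering-induced turning
    cruise_speed_mean: float = 18.0       # m/s
    cruise_speed_sd: float = 0.5
    min_speed: float = 5.0
    max_speed: float = 35.0

    gamma_angle_shape: float = 2.0        # manoeuvre angle ~ Gamma(shape, scale), deg
    gamma_angle_scale: float = 30.0
    gamma_duration_shape: float = 3.0     # manoeuvre duration ~ Gamma(shape, scale), s
    gamma_duration_scale: float = 0.6
    escape_distance_scale: float = 30.0   # m, decay of manoeuvre probability
    tendency_min: float = 1.25e-3         # per-update baseline escape tendency
    tendency_max: float = 1e-2

    cycle_duration: float = 60.0          # s, one hunting cycle
    output_rate: float = 5.0              # Hz, track sampling
    warmup_s: float = 15.0                # s, un-recorded settling before the cycle
    init_radius: Optional[float] = None   # m, initial disc; None = density-scaled
    heading_jitter_sd_deg: float = 5.0
    seed: int = 0

    predator: PredatorParams = field(default_factory=PredatorParams)

    def __post_init__(self) -> None:
        if self.n_pigeons < 1:
            raise ConfigError("n_pigeons must be >= 1")
        if self.n_topological < 1:
            raise ConfigError("n_topological must be >= 1")
        if self.dt <= 0 or self.reaction_interval <= 0:
            raise ConfigError("dt and reaction_interval must be positive")
        if self.dt > self.reaction_interval + 1e-12:
            raise ConfigError("dt must not exceed reaction_interval")
        for name in ("weight_alignment", "weight_attraction", "weight_separation",
                     "weight_cruise", "weight_catchup", "weight_predator_avoidance"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (self.weight_alignment >= self.weight_attraction
                and self.weight_alignment >= self.weight_separation):
            raise ConfigError("alignment must be the strongest coordination force")
        for name in ("gamma_angle_shape", "gamma_angle_scale",
                     "gamma_duration_shape", "gamma_duration_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.escape_distance_scale <= 0:
            raise ConfigError("escape_distance_scale must be positive")
        if not 0.0 < self.avoidance_cap <= 1.0:
            raise ConfigError("avoidance_cap must be in (0, 1]")
        if not 0.0 <= self.tendency_min <= self.tendency_max <= 1.0:
            raise ConfigError("escape tendencies must satisfy 0 <= min <= max <= 1")
        if self.cruise_speed_mean <= 0 or self.cruise_speed_sd < 0:
            raise ConfigError("cruise speed parameters out of range")
        if not 0 < self.min_speed < self.max_speed:
            raise ConfigError("need 0 < min_speed < max_speed")
        if self.cycle_duration <= 0 or self.output_rate <= 0:
            raise ConfigError("cycle_duration and output_rate must be positive")
        if self.warmup_s < 0:
            raise ConfigError("warmup_s must be >= 0")
        if self.init_radius is not None and self.init_radius <= 0:
            raise ConfigError("init_radius must be positive")
        if self.max_interaction_distance <= 0 or self.separation_radius <= 0:
            raise ConfigError("interaction distances must be positive")
        if self.attraction_saturation <= 0:
            raise ConfigError("attraction_saturation must be positive")

    @property
    def effective_init_radius(self) -> float:
        """Initial-disc radius: explicit, or scaled to realistic flock density."""
        if self.init_radius is not None:
            return self.init_radius
        return max(2.5, 1.1 * float(np.sqrt(self.n_pigeons)))

    @property
    def output_stride(self) -> int:
        """Integration steps between written track samples."""
        stride = round(1.0 / (self.output_rate * self.dt))
        return max(stride, 1)


@dataclass(frozen=True)
class DetectConfig:
    """Parameters of the trajectory-analysis procedures.

    ``straight_threshold`` separates collective turns from straight
    flight on the centroid trajectory; a flock member is split once no
    main-flock member is within ``split_distance`` for at least
    ``split_min_duration``.  Flocks of at most ``small_flock_max_size``
    individuals form the small size class for centrality normalization.
    """

    straight_threshold: float = 10.0    # deg/s
    split_distance: float = 10.0        # m
    split_min_duration: float = 2.0     # s
    small_flock_max_size: int = 10
    attribution_window: float = 2.0     # s beyond manoeuvre end
    dead_band: float = 0.5              # deg/s, sign-neutral angular velocity
    simultaneity_window: float = 1.0    # s, grouping of joint departures

    def __post_init__(self) -> None:
        for name in ("straight_threshold", "split_distance", "split_min_duration",
                     "attribution_window", "simultaneity_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.small_flock_max_size < 1:
            raise ConfigError("small_flock_max_size must be >= 1")
        if self.dead_band < 0:
            raise ConfigError("dead_band must be >= 0")


_PRED_FIELDS = {f.name for f in dataclasses.fields(PredatorParams)}
_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)} - {"predator"}
_DETECT_FIELDS = {f.name for f in dataclasses.fields(DetectConfig)}


def _coerce(raw: dict[str, Any]) -> dict[str, Any]:
    out = dict(raw)
    if "phase_fractions" in out and isinstance(out["phase_fractions"], list):
        out["phase_fractions"] = tuple(out["phase_fractions"])
    return out


def load_config(path: str | Path, kind: str = "sim") -> SimConfig | DetectConfig:
    """Load a flat key-value config file into a validated config object.

    Keys mirror the dataclass field names exactly; predator parameters
    sit at top level alongside the flock parameters (``kind='sim'``).
    Unknown keys are rejected; absent keys take their defaults; an
    empty file yields a pure-defaults configuration.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected flat key-value pairs")
    raw = _coerce(raw)
    if kind == "detect":
        unknown = set(raw) - _DETECT_FIELDS
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        return DetectConfig(**raw)
    if kind != "sim":
        raise ConfigError(f"unknown config kind {kind!r}")
    unknown = set(raw) - _SIM_FIELDS - _PRED_FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    pred_kwargs = {k: v for k, v in raw.items() if k in _PRED_FIELDS}
    sim_kwargs = {k: v for k, v in raw.items() if k in _SIM_FIELDS}
    return SimConfig(predator=PredatorParams(**pred_kwargs), **sim_kwargs)


def config_to_dict(cfg: SimConfig | DetectConfig) -> dict[str, Any]:
    """Flatten a config object to the key-value form used in manifests."""
    d = dataclasses.asdict(cfg)
    pred = d.pop("predator", None)
    if pred is not None:
        d.update(pred)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    return d


def config_hash(*cfgs: SimConfig | DetectConfig) -> str:
    """Deterministic short hash of one or more configs, for run manifests."""
    payload = json.dumps([config_to_dict(c) for c in cfgs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
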