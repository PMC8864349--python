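"""Scaled-down replication of the simulation study's headline contrasts.

Runs batches of hunting cycles across the empirical flock sizes
(8, 10, 27, 34), pools the detected events, and summarises the three
initiator-effect quantities the model is judged on:

* the relative increase in per-manoeuvre split probability for
  above-median ("sharp") versus below-median angular-velocity
  manoeuvres;
* the relative increase in per-manoeuvre collective-turn probability
  for central versus edge initiators;
* the share of split events that are sub-flock departures rather than
  solitary ones.

Each quantity is computed per base seed and averaged, so seed-to-seed
spread is visible alongside the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import DetectConfig, SimConfig
from .stats import BatchSpec, EventTable, pattern_rates, run_batch, trait_contrast

__all__ = ["EffectSummary", "batch_effects", "trait_effect_summary",
           "control_split_rate", "derive_seeds"]

EMPIRICAL_FLOCK_SIZES = (8, 10, 27, 34)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Independent 31-bit batch seeds derived from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s % (2 ** 31 - 1)) for s in state]


@dataclass
class EffectSummary:
    """Per-seed values and their mean for the three headline effects."""

    sharp_turn_split_increase_pct: list[float] = field(default_factory=list)
    central_turn_increase_pct: list[float] = field(default_factory=list)
    subflock_split_share_pct: list[float] = field(default_factory=list)
    n_cycles_total: int = 0
    n_manoeuvres_total: int = 0

    def mean(self, name: str) -> float:
        vals = [v for v in getattr(self, name) if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def batch_effects(events: EventTable) -> dict[str, float]:
    """The three effect quantities for one pooled batch."""
    av = trait_contrast(events, "ang_vel")
    cent = trait_contrast(events, "centrality")
    splits = events.splits
    share = (100.0 * float((splits["size"] >= 2).mean())
             if len(splits) else float("nan"))
    return {
        "sharp_turn_split_increase_pct": av.rel_increase_split,
        "central_turn_increase_pct": cent.rel_increase_turn,
        "subflock_split_share_pct": share,
    }


def trait_effect_summary(master_seed: int, n_seeds: int = 5,
                         n_cycles: int = 100,
                         flock_sizes: Sequence[int] = EMPIRICAL_FLOCK_SIZES,
                         cfg: Optional[SimConfig] = None,
                         detect: Optional[DetectConfig] = None) -> EffectSummary:
    """Run ``n_seeds`` independent batches and summarise the effects."""
    cfg = cfg or SimConfig()
    detect = detect or DetectConfig()
    out = EffectSummary()
    for seed in derive_seeds(master_seed, n_seeds):
        spec = BatchSpec(n_cycles=n_cycles, flock_sizes=tuple(flock_sizes),
                         predator_enabled=True, base_seed=seed, cfg=cfg,
                         detect=detect)
        events = run_batch(spec)
        eff = batch_effects(events)
        out.sharp_turn_split_increase_pct.append(
            eff["sharp_turn_split_increase_pct"])
        out.central_turn_increase_pct.append(eff["central_turn_increase_pct"])
        out.subflock_split_share_pct.append(eff["subflock_split_share_pct"])
        out.n_cycles_total += n_cycles
        out.n_manoeuvres_total += len(events.manoeuvres)
    return out


def control_split_rate(master_seed: int, n_flights: int = 16,
                       flock_sizes: Sequence[int] = EMPIRICAL_FLOCK_SIZES,
                       cfg: Optional[SimConfig] = None,
                       detect: Optional[DetectConfig] = None) -> float:
    """Across-flight median splitting rate of predator-free flights."""
    cfg = cfg or SimConfig()
    detect = detect or DetectConfig()
    spec = BatchSpec(n_cycles=n_flights, flock_sizes=tuple(flock_sizes),
                     predator_enabled=False,
                     base_seed=derive_seeds(master_seed, 1)[0],
                     cfg=cfg, detect=detect)
    events = run_batch(spec)
    _, medians = pattern_rates(events)
    return medians["split_rate"]
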