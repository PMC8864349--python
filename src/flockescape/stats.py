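"""Batch simulation driver and the statistical contrasts.

Runs many independent hunting cycles (fresh flock each time, sizes
drawn round-robin from the configured multiset), applies the detectors
to every cycle, and pools everything into one event dataset before any
median split — trait labels (central/edge, low/high angular velocity)
are defined on the pooled distribution, and centrality is normalized by
the mean raw centrality of each flock-size class across the whole
batch.  Provides per-flight pattern rates with across-flight medians,
2x2 trait-versus-outcome contrasts with Pearson chi-squared tests, and
two-sample Kolmogorov-Smirnov comparisons between predator and control
flights.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DetectConfig, SimConfig
from .detect import (ManoeuvreRecord, attribute_outcomes, detect_splits,
                     centroid_trajectory, raw_centrality_table, segment_turns,
                     turning_metrics, label_initiator)
from .simulate import simulate_cycle

__all__ = [
    "BatchSpec",
    "EventTable",
    "TraitContrast",
    "run_batch",
    "pattern_rates",
    "trait_contrast",
    "centrality_ks",
    "compare_control",
]

RATE_METRICS = ["time_turning_fraction", "angle_per_second", "turn_rate", "split_rate"]


@dataclass(frozen=True)
class BatchSpec:
    """Specification of one batch of independent hunting cycles."""

    n_cycles: int
    flock_sizes: tuple[int, ...] = (8, 10, 27, 34)
    predator_enabled: bool = True
    base_seed: int = 0
    cfg: SimConfig = field(default_factory=SimConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not self.flock_sizes:
            raise ValueError("flock_sizes must be non-empty")


@dataclass
class EventTable:
    """Pooled per-batch results.

    manoeuvres: one row per escape manoeuvre with traits and outcome;
    splits: one row per split event; cycles: per-flight metrics.
    """

    manoeuvres: pd.DataFrame
    splits: pd.DataFrame
    cycles: pd.DataFrame
    spec: Optional[BatchSpec] = None


def _size_class(n: int, detect: DetectConfig) -> str:
    return "small" if n <= detect.small_flock_max_size else "large"


def run_batch(spec: BatchSpec) -> EventTable:
    """Run the batch and pool all detected events into one dataset."""
    ss = np.random.SeedSequence(spec.base_seed)
    children = ss.spawn(spec.n_cycles)
    man_rows: list[dict] = []
    split_rows: list[dict] = []
    cycle_rows: list[dict] = []
    # raw-centrality normalization accumulators per size class
    cent_sum = {"small": 0.0, "large": 0.0}
    cent_n = {"small": 0, "large": 0}

    for c in range(spec.n_cycles):
        size = spec.flock_sizes[c % len(spec.flock_sizes)]
        cfg = dataclasses.replace(spec.cfg, n_pigeons=size)
        res = simulate_cycle(cfg, seed=children[c],
                             predator_enabled=spec.predator_enabled, cycle_id=c)
        tracks = res.tracks
        klass = _size_class(size, spec.detect)

        raw = raw_centrality_table(tracks)
        cent_sum[klass] += float(raw["raw_centrality"].sum())
        cent_n[klass] += len(raw)

        splits = detect_splits(tracks, spec.detect)
        duration = float(tracks["t_s"].max() - tracks["t_s"].min())
        segments = segment_turns(centroid_trajectory(tracks), spec.detect)
        metrics = turning_metrics(segments, duration)
        cycle_rows.append({
            "cycle": c, "flock_size": size, "size_class": klass,
            "duration_s": duration, "n_splits": len(splits),
            "split_rate": len(splits) / duration, **metrics,
        })
        for ev in splits:
            split_rows.append({
                "cycle": c, "flock_size": size, "size_class": klass,
                "t_start_s": ev.t_start, "size": ev.size, "kind": ev.kind,
                "merged_back_at": ev.merged_back_at,
            })

        records = [
            ManoeuvreRecord(
                cycle_id=c,
                initiator_id=int(r.initiator_id),
                t_start=float(r.t_start_s),
                total_angle=float(r.total_angle_deg),
                duration=float(r.duration_s),
                ang_vel=float(r.ang_vel_deg_s),
                dist_to_pred=float(r.dist_to_pred_m),
            )
            for r in res.manoeuvres.itertuples()
        ]
        records = attribute_outcomes(records, tracks, spec.detect, splits=splits)
        times = np.sort(tracks["t_s"].unique())
        for rec in records:
            f_t = times[np.argmin(np.abs(times - rec.t_start))]
            row = raw[(raw["t_s"] == f_t) & (raw["agent_id"] == rec.initiator_id)]
            raw_cent = float(row["raw_centrality"].iloc[0])
            rec = label_initiator(rec, tracks, {})   # direction label only here
            man_rows.append({
                "cycle": c, "flock_size": size, "size_class": klass,
                "initiator_id": rec.initiator_id, "t_start_s": rec.t_start,
                "total_angle_deg": rec.total_angle, "duration_s": rec.duration,
                "ang_vel_deg_s": rec.ang_vel, "dist_to_pred_m": rec.dist_to_pred,
                "raw_centrality": raw_cent, "direction_label": rec.direction_label,
                "outcome": rec.outcome,
            })

    manoeuvres = pd.DataFrame(man_rows, columns=[
        "cycle", "flock_size", "size_class", "initiator_id", "t_start_s",
        "total_angle_deg", "duration_s", "ang_vel_deg_s", "dist_to_pred_m",
        "raw_centrality", "direction_label", "outcome"])
    splits_df = pd.DataFrame(split_rows, columns=[
        "cycle", "flock_size", "size_class", "t_start_s", "size", "kind",
        "merged_back_at"])
    cycles_df = pd.DataFrame(cycle_rows)

    # pooled normalization and median-split labels
    if len(manoeuvres):
        class_mean = {k: (cent_sum[k] / cent_n[k]) if cent_n[k] else np.nan
                      for k in cent_sum}
        manoeuvres["centrality"] = [
            r.raw_centrality / class_mean[r.size_class]
            for r in manoeuvres.itertuples()]
        classified = manoeuvres["outcome"] != "excluded"
        med_cent = float(manoeuvres.loc[classified, "centrality"].median())
        med_av = float(manoeuvres.loc[classified, "ang_vel_deg_s"].abs().median())
        manoeuvres["centrality_label"] = np.where(
            manoeuvres["centrality"] < med_cent, "central", "edge")
        manoeuvres["ang_vel_label"] = np.where(
            manoeuvres["ang_vel_deg_s"].abs() > med_av, "high", "low")
    else:
        manoeuvres["centrality"] = pd.Series(dtype=float)
        manoeuvres["centrality_label"] = pd.Series(dtype=object)
        manoeuvres["ang_vel_label"] = pd.Series(dtype=object)
    return EventTable(manoeuvres=manoeuvres, splits=splits_df,
                      cycles=cycles_df, spec=spec)


def pattern_rates(events: EventTable) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-flight metrics and their across-flight medians.

    The median is used as the summary because the per-flight
    distributions are highly skewed.
    """
    per_cycle = events.cycles.copy()
    if per_cycle.empty:
        raise ValueError("no flights in event table")
    medians = {m: float(per_cycle[m].median()) for m in RATE_METRICS}
    return per_cycle, medians


_TRAIT_COLUMNS = {
    "ang_vel": ("ang_vel_label", ("high", "low")),
    "centrality": ("centrality_label", ("central", "edge")),
    "direction": ("direction_label", ("outwards", "inwards")),
}


@dataclass
class TraitContrast:
    """2x2 trait-level x outcome contrast.

    ``rel_increase_split`` and ``rel_increase_turn`` are the relative
    changes (percent) of the per-manoeuvre split and collective-turn
    probabilities of the first trait level versus the second, e.g.
    (P(split | high) - P(split | low)) / P(split | low) * 100.
    """

    trait: str
    levels: tuple[str, str]
    table: pd.DataFrame          # rows: levels, cols: split / collective_turn
    chi2: float
    p_value: float
    dof: int
    n_none: int                  # manoeuvres with neither pattern (excluded)
    rel_increase_split: float
    rel_increase_turn: float


def trait_contrast(events: EventTable, trait: str,
                   correction: bool = False) -> TraitContrast:
    """Pearson chi-squared contrast of outcome by a median-split trait.

    Manoeuvres whose outcome is neither split nor collective turn are
    excluded from the 2x2 table but counted in ``n_none``.
    """
    if trait not in _TRAIT_COLUMNS:
        raise ValueError(f"unknown trait {trait!r}")
    col, levels = _TRAIT_COLUMNS[trait]
    df = events.manoeuvres
    df = df[df["outcome"].isin(["split", "collective_turn"])]
    n_none = int((events.manoeuvres["outcome"] == "none").sum())
    table = pd.DataFrame(0, index=list(levels), columns=["split", "collective_turn"])
    for level in levels:
        sub = df[df[col] == level]
        table.loc[level, "split"] = int((sub["outcome"] == "split").sum())
        table.loc[level, "collective_turn"] = int(
            (sub["outcome"] == "collective_turn").sum())
    arr = table.to_numpy(dtype=float)
    if arr.sum() == 0 or (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        chi2, p, dof = np.nan, np.nan, 1
    else:
        chi2, p, dof, _ = sps.chi2_contingency(arr, correction=correction)
        if np.allclose(arr.sum(axis=1).reshape(-1, 1) * arr.sum(axis=0)
                       / arr.sum(), arr):
            chi2, p = 0.0, 1.0      # identical proportions exactly
    totals = arr.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_split = arr[:, 0] / totals
        p_turn = arr[:, 1] / totals
    rel = lambda p_: float((p_[0] - p_[1]) / p_[1] * 100.0) if p_[1] > 0 else np.nan
    return TraitContrast(
        trait=trait, levels=levels, table=table,
        chi2=float(chi2), p_value=float(p), dof=int(dof), n_none=n_none,
        rel_increase_split=rel(p_split), rel_increase_turn=rel(p_turn),
    )


def centrality_ks(events: EventTable) -> tuple[float, float]:
    """Two-sided KS test of initiator centrality: split vs collective turn."""
    df = events.manoeuvres
    a = df.loc[df["outcome"] == "split", "centrality"].to_numpy()
    b = df.loc[df["outcome"] == "collective_turn", "centrality"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both outcome classes are required for the KS test")
    res = sps.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_control(events_pred: EventTable,
                    events_ctrl: EventTable) -> pd.DataFrame:
    """Metric-wise two-sample KS tests: predator vs control flights.

    For each per-flight metric (time-turning fraction, angle per
    second, turning rate, splitting rate) the two across-flight value
    distributions are compared; returns D and p per metric.
    """
    rows = []
    for metric in RATE_METRICS:
        a = events_pred.cycles[metric].to_numpy(dtype=float)
        b = events_ctrl.cycles[metric].to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both batches must contain flights")
        res = sps.ks_2samp(a, b, alternative="two-sided")
        rows.append({"metric": metric, "D": float(res.statistic),
                     "p_value": float(res.pvalue),
                     "median_pred": float(np.median(a)),
                     "median_ctrl": float(np.median(b))})
    return pd.DataFrame(rows)
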