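"""Measurement machinery for flock trajectories.

Operates identically on simulated tracks and GPS-like tables: headings
are always recovered from finite differences of position, so the
simulator's internal headings are ignored.  Provides centroid-trajectory
turn segmentation (sign-consistent angular-velocity intervals, straight
below 10 deg/s), the 10 m / 2 s split detector with simultaneous
departures grouped into single events, centrality measures, initiator
trait labelling, and attribution of escape manoeuvres to the emergent
pattern (split, collective turn, or neither).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .config import DetectConfig
from .geometry import wrap_deg

__all__ = [
    "TurnSegment",
    "SplitEvent",
    "ManoeuvreRecord",
    "centroid_trajectory",
    "segment_turns",
    "turning_metrics",
    "detect_splits",
    "raw_centrality_table",
    "centrality",
    "label_initiator",
    "classify_outcome",
    "attribute_outcomes",
    "main_flock_at",
]


@dataclass(frozen=True)
class TurnSegment:
    """A sign-consistent interval of the (centroid) trajectory."""

    t_start: float
    t_end: float
    cum_angle: float      # deg, signed cumulative heading change
    ang_vel: float        # deg/s, |cum_angle| / duration
    label: str            # 'turn' or 'straight'

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SplitEvent:
    """A departure (individual or sub-flock, counted once) from the main flock."""

    t_start: float
    member_ids: frozenset
    size: int
    kind: str             # 'solitary' or 'sub-flock'
    merged_back_at: Optional[float] = None


@dataclass
class ManoeuvreRecord:
    """One discrete escape manoeuvre and its initiator's traits.

    ``ang_vel`` is signed (positive = left turn); trait labels are
    median splits over the pooled event dataset; ``outcome`` is the
    collective pattern the manoeuvre gave rise to, or ``'excluded'``
    when the initiator was not in the main flock at onset.
    """

    cycle_id: int
    initiator_id: int
    t_start: float
    total_angle: float
    duration: float
    ang_vel: float
    dist_to_pred: float
    centrality: Optional[float] = None
    centrality_label: Optional[str] = None   # 'central' / 'edge'
    direction_label: Optional[str] = None    # 'inwards' / 'outwards'
    ang_vel_label: Optional[str] = None      # 'low' / 'high'
    outcome: Optional[str] = None            # 'split' / 'collective_turn' / 'none'


# ---------------------------------------------------------------------------
# track-table helpers

def _prey_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    if "is_predator" in tracks.columns:
        return tracks[tracks["is_predator"] == 0]
    return tracks


def _grid(tracks: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pivot prey rows into (times, agent_ids, positions[T, A, 2])."""
    df = _prey_tracks(tracks)
    px = df.pivot(index="t_s", columns="agent_id", values="x_m")
    py = df.pivot(index="t_s", columns="agent_id", values="y_m")
    if px.isna().any().any():
        raise ValueError("tracks are not a complete time x agent grid")
    times = px.index.to_numpy(dtype=float)
    agents = px.columns.to_numpy(dtype=int)
    xyz = np.stack([px.to_numpy(dtype=float), py.to_numpy(dtype=float)], axis=-1)
    return times, agents, xyz


def _nearest_frame(times: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(times - t)))


def centroid_trajectory(tracks: pd.DataFrame, members: Optional[set] = None) -> pd.DataFrame:
    """Trajectory of the mean position of ``members`` (default: all prey).

    Returns a single-agent track table with columns t_s, x_m, y_m.
    """
    df = _prey_tracks(tracks)
    if members is not None:
        if not members:
            raise ValueError("members must be non-empty")
        df = df[df["agent_id"].isin(members)]
    out = df.groupby("t_s", sort=True)[["x_m", "y_m"]].mean().reset_index()
    return out


# ---------------------------------------------------------------------------
# turn segmentation

def _headings_from_displacements(xy: np.ndarray) -> np.ndarray:
    """Heading (deg) of each successive displacement; stationary samples
    carry the heading of the last moving sample forward (and the first
    moving heading backward over any leading stationary stretch)."""
    disp = np.diff(xy, axis=0)
    moving = np.linalg.norm(disp, axis=1) > 1e-9
    if not moving.any():
        raise ValueError("trajectory never moves; headings undefined")
    h = np.degrees(np.arctan2(disp[:, 1], disp[:, 0]))
    idx = np.where(moving, np.arange(len(h)), -1)
    idx = np.maximum.accumulate(idx)
    first = int(np.argmax(moving))
    idx[idx < 0] = first
    return h[idx]


def segment_turns(traj: pd.DataFrame, cfg: Optional[DetectConfig] = None) -> list[TurnSegment]:
    """Divide a single trajectory into sign-consistent turning intervals.

    Headings come from finite differences of position.  Per-sample
    angular velocities inside the dead band are sign-neutral: a neutral
    stretch bridging two same-sign turning runs is merged into them,
    while neutral stretches at the ends or between opposite-sign runs
    stand as their own (straight) segments.  Each segment is labelled
    ``straight`` when its average angular velocity is below the
    straight threshold, else ``turn``.  Segments tile the trajectory
    (to one sample period).
    """
    cfg = cfg or DetectConfig()
    t = traj["t_s"].to_numpy(dtype=float)
    xy = traj[["x_m", "y_m"]].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples to segment turns")
    dt = float(np.median(np.diff(t)))
    h = _headings_from_displacements(xy)
    dtheta = wrap_deg(h[1:] - h[:-1])          # length N-2
    omega = dtheta / dt
    sign = np.sign(dtheta).astype(int)
    sign[np.abs(omega) < cfg.dead_band] = 0

    # run-length encode, then bridge neutral runs between same-sign runs
    runs: list[list] = []                       # [sign, start_idx, end_idx]
    for j, s in enumerate(sign):
        if runs and runs[-1][0] == s:
            runs[-1][2] = j
        else:
            runs.append([int(s), j, j])
    merged = True
    while merged:
        merged = False
        for k in range(1, len(runs) - 1):
            if runs[k][0] == 0 and runs[k - 1][0] == runs[k + 1][0] != 0:
                runs[k - 1][2] = runs[k + 1][2]
                del runs[k:k + 2]
                merged = True
                break

    segments = []
    for s, a, b in runs:
        t0, t1 = float(t[a]), float(t[b + 1])
        cum = float(dtheta[a:b + 1].sum())
        ang_vel = abs(cum) / (t1 - t0)
        label = "straight" if ang_vel < cfg.straight_threshold else "turn"
        segments.append(TurnSegment(t0, t1, cum, ang_vel, label))
    return segments


def turning_metrics(segments: Sequence[TurnSegment],
                    flight_duration: float) -> dict[str, float]:
    """Per-flight turning summary.

    turn_rate: turn-labelled segments per second of flight;
    time_turning_fraction: total turn-segment time over flight time;
    angle_per_second: total absolute turned angle over flight time.
    """
    turns = [s for s in segments if s.label == "turn"]
    return {
        "turn_rate": len(turns) / flight_duration,
        "time_turning_fraction": sum(s.duration for s in turns) / flight_duration,
        "angle_per_second": sum(abs(s.cum_angle) for s in turns) / flight_duration,
    }


# ---------------------------------------------------------------------------
# split detection

def _components(frame_xy: np.ndarray, threshold: float) -> np.ndarray:
    """Connected-component label per agent under the <= threshold adjacency."""
    d = np.linalg.norm(frame_xy[:, None, :] - frame_xy[None, :, :], axis=-1)
    adj = csr_matrix(d <= threshold)
    _, labels = connected_components(adj, directed=False)
    return labels


def _main_component(labels: np.ndarray, agents: np.ndarray) -> int:
    """Largest component; ties go to the component holding the lowest id."""
    comp_ids, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    tied = comp_ids[counts == best]
    if len(tied) == 1:
        return int(tied[0])
    min_ids = [agents[labels == c].min() for c in tied]
    return int(tied[int(np.argmin(min_ids))])


def main_flock_at(tracks: pd.DataFrame, t: float,
                  cfg: Optional[DetectConfig] = None) -> set[int]:
    """Members of the main flock (largest connected group) at time ``t``."""
    cfg = cfg or DetectConfig()
    times, agents, xyz = _grid(tracks)
    f = _nearest_frame(times, t)
    labels = _components(xyz[f], cfg.split_distance)
    main = _main_component(labels, agents)
    return set(agents[labels == main].tolist())


def detect_splits(tracks: pd.DataFrame,
                  cfg: Optional[DetectConfig] = None) -> list[SplitEvent]:
    """Find all departures from the main flock.

    Per frame, agents partition into connected components under the
    split-distance adjacency and the largest component is the main
    flock.  An individual is split once it stays outside the main
    flock's split-distance neighbourhood continuously for at least the
    minimum split duration; the event is stamped at the excursion
    start.  Individuals departing together (excursion starts within the
    simultaneity window and mutually connected) form one sub-flock
    event; a merge time is recorded when the criterion re-inverts.
    """
    cfg = cfg or DetectConfig()
    times, agents, xyz = _grid(tracks)
    n_t, n_a = xyz.shape[:2]
    if n_a < 2:
        return []
    away = np.zeros((n_t, n_a), dtype=bool)
    for f in range(n_t):
        labels = _components(xyz[f], cfg.split_distance)
        main = _main_component(labels, agents)
        away[f] = labels != main

    # qualifying excursions per agent: (agent_idx, frame_start, frame_end)
    excursions = []
    for a in range(n_a):
        flags = away[:, a]
        starts = np.flatnonzero(flags & ~np.r_[False, flags[:-1]])
        ends = np.flatnonzero(flags & ~np.r_[flags[1:], False])
        for i0, i1 in zip(starts, ends):
            if times[i1] - times[i0] >= cfg.split_min_duration - 1e-9:
                merge = float(times[i1 + 1]) if i1 + 1 < n_t else None
                excursions.append((a, int(i0), int(i1), merge))
    excursions.sort(key=lambda e: (times[e[1]], agents[e[0]]))

    # cluster simultaneous departures, then group by connectivity
    events: list[SplitEvent] = []
    cluster: list[tuple] = []

    def flush(cluster: list[tuple]) -> None:
        if not cluster:
            return
        k = len(cluster)
        adj = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(i, k):
                f = max(cluster[i][1], cluster[j][1])
                d = np.linalg.norm(xyz[f, cluster[i][0]] - xyz[f, cluster[j][0]])
                adj[i, j] = adj[j, i] = d <= cfg.split_distance
        _, labels = connected_components(csr_matrix(adj), directed=False)
        for c in np.unique(labels):
            group = [cluster[i] for i in np.flatnonzero(labels == c)]
            members = frozenset(int(agents[g[0]]) for g in group)
            merges = [g[3] for g in group]
            merged = max(merges) if all(m is not None for m in merges) else None
            t0 = min(float(times[g[1]]) for g in group)
            events.append(SplitEvent(
                t_start=t0,
                member_ids=members,
                size=len(members),
                kind="solitary" if len(members) == 1 else "sub-flock",
                merged_back_at=merged,
            ))

    for exc in excursions:
        if cluster and times[exc[1]] - times[cluster[0][1]] > cfg.simultaneity_window:
            flush(cluster)
            cluster = []
        cluster.append(exc)
    flush(cluster)
    events.sort(key=lambda e: (e.t_start, min(e.member_ids)))
    return events


# ---------------------------------------------------------------------------
# centrality

def raw_centrality_table(tracks: pd.DataFrame) -> pd.DataFrame:
    """Distance of every agent to the flock centroid at every time.

    Columns: t_s, agent_id, raw_centrality.
    """
    times, agents, xyz = _grid(tracks)
    cent = xyz.mean(axis=1, keepdims=True)
    raw = np.linalg.norm(xyz - cent, axis=-1)
    return pd.DataFrame({
        "t_s": np.repeat(times, len(agents)),
        "agent_id": np.tile(agents, len(times)),
        "raw_centrality": raw.ravel(),
    })


def centrality(tracks: pd.DataFrame, agent_id: int, t: float,
               normalization_mean: Optional[float] = None) -> float:
    """Normalized centrality of one agent at one time.

    Raw centrality is the distance to the flock centroid; it is divided
    by the mean raw centrality over all individuals and times of the
    flock's size class (by default, over this track table), so the
    normalized values average 1 within a class.
    """
    table = raw_centrality_table(tracks)
    if normalization_mean is None:
        normalization_mean = float(table["raw_centrality"].mean())
    times = table["t_s"].to_numpy()
    f_t = times[_nearest_frame(np.unique(times), t)]
    row = table[(table["t_s"] == f_t) & (table["agent_id"] == agent_id)]
    if row.empty:
        raise ValueError(f"agent {agent_id} absent at t={t}")
    raw = float(row["raw_centrality"].iloc[0])
    if normalization_mean == 0.0:
        return 0.0
    return raw / normalization_mean


# ---------------------------------------------------------------------------
# initiator labels and outcome attribution

def _heading_at_onset(tracks: pd.DataFrame, agent_id: int, t: float) -> float:
    """Finite-difference heading of one agent just before time ``t``."""
    df = _prey_tracks(tracks)
    df = df[df["agent_id"] == agent_id].sort_values("t_s")
    xy = df[["x_m", "y_m"]].to_numpy(dtype=float)
    times = df["t_s"].to_numpy(dtype=float)
    f = _nearest_frame(times, t)
    f = max(f, 1)
    disp = xy[f] - xy[f - 1]
    if np.linalg.norm(disp) < 1e-9:
        h = _headings_from_displacements(xy)
        return float(h[min(f - 1, len(h) - 1)])
    return float(np.degrees(np.arctan2(disp[1], disp[0])))


def label_initiator(record: ManoeuvreRecord, tracks: pd.DataFrame,
                    dataset_medians: dict[str, float]) -> ManoeuvreRecord:
    """Attach median-split trait labels to a manoeuvre record.

    ``dataset_medians`` holds ``centrality`` and ``ang_vel`` medians
    computed over the full pooled event dataset.  The direction label
    is ``inwards`` when the signed turn rotates the initiator's heading
    toward the bearing of the flock centroid at onset (degenerate
    geometry, e.g. an initiator at the centroid, breaks to
    ``outwards``).
    """
    rec = replace(record) if isinstance(record, ManoeuvreRecord) else record
    if rec.centrality is not None and "centrality" in dataset_medians:
        rec.centrality_label = (
            "central" if rec.centrality < dataset_medians["centrality"] else "edge")
    if "ang_vel" in dataset_medians:
        rec.ang_vel_label = (
            "high" if abs(rec.ang_vel) > dataset_medians["ang_vel"] else "low")

    cent = centroid_trajectory(tracks)
    times = cent["t_s"].to_numpy(dtype=float)
    f = _nearest_frame(times, rec.t_start)
    c_xy = cent[["x_m", "y_m"]].to_numpy(dtype=float)[f]
    df = _prey_tracks(tracks)
    row = df[(df["agent_id"] == rec.initiator_id)
             & (np.isclose(df["t_s"], times[f]))]
    p_xy = row[["x_m", "y_m"]].to_numpy(dtype=float)[0]
    to_centre = c_xy - p_xy
    if np.linalg.norm(to_centre) < 1e-9:
        rec.direction_label = "outwards"
        return rec
    heading = _heading_at_onset(tracks, rec.initiator_id, rec.t_start)
    bearing = float(np.degrees(np.arctan2(to_centre[1], to_centre[0])))
    delta = wrap_deg(bearing - heading)
    turn_sign = np.sign(rec.ang_vel)
    rec.direction_label = (
        "inwards" if delta != 0 and np.sign(delta) == turn_sign else "outwards")
    return rec


def _overlaps(seg: TurnSegment, t0: float, t1: float) -> bool:
    return seg.t_start < t1 and seg.t_end > t0


def attribute_outcomes(records: Sequence[ManoeuvreRecord], tracks: pd.DataFrame,
                       cfg: Optional[DetectConfig] = None,
                       splits: Optional[list[SplitEvent]] = None) -> list[ManoeuvreRecord]:
    """Assign an emergent-pattern outcome to every manoeuvre of a cycle.

    Within the window from manoeuvre onset to its end plus the
    attribution window: ``split`` if a split event starting in the
    window contains the initiator; otherwise ``collective_turn`` if the
    main flock's centroid trajectory has a turn-labelled segment of
    matching sign overlapping the window; otherwise ``none``.  Only
    initiators that start inside the main flock are classified (others
    get ``excluded``), and a given split event or centroid turn is
    credited only once, to the earliest-onset manoeuvre.
    """
    cfg = cfg or DetectConfig()
    if splits is None:
        splits = detect_splits(tracks, cfg)
    out = []
    claimed_splits: set[int] = set()
    claimed_turns: set[tuple] = set()
    seg_cache: dict[frozenset, list[TurnSegment]] = {}

    for rec in sorted(records, key=lambda r: r.t_start):
        rec = replace(rec)
        main = main_flock_at(tracks, rec.t_start, cfg)
        if rec.initiator_id not in main:
            rec.outcome = "excluded"
            out.append(rec)
            continue
        w0 = rec.t_start
        w1 = rec.t_start + rec.duration + cfg.attribution_window
        hit = None
        for k, ev in enumerate(splits):
            if k in claimed_splits:
                continue
            if w0 - 1e-9 <= ev.t_start <= w1 and rec.initiator_id in ev.member_ids:
                hit = k
                break
        if hit is not None:
            claimed_splits.add(hit)
            rec.outcome = "split"
            out.append(rec)
            continue
        key = frozenset(main)
        if key not in seg_cache:
            seg_cache[key] = segment_turns(centroid_trajectory(tracks, main), cfg)
        turn_sign = np.sign(rec.ang_vel)
        found = False
        for seg in seg_cache[key]:
            if seg.label != "turn" or not _overlaps(seg, w0, w1):
                continue
            if np.sign(seg.cum_angle) != turn_sign:
                continue
            tkey = (key, round(seg.t_start, 6))
            if tkey in claimed_turns:
                continue
            claimed_turns.add(tkey)
            found = True
            break
        rec.outcome = "collective_turn" if found else "none"
        out.append(rec)
    out.sort(key=lambda r: (r.t_start, r.initiator_id))
    return out


def classify_outcome(record: ManoeuvreRecord, tracks: pd.DataFrame,
                     cfg: Optional[DetectConfig] = None) -> str:
    """Outcome of a single manoeuvre (see :func:`attribute_outcomes`)."""
    return attribute_outcomes([record], tracks, cfg)[0].outcome
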