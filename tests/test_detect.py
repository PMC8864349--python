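"""Turn segmentation, split detection, centrality and outcome attribution."""

import numpy as np
import pandas as pd
import pytest

from flockescape import DetectConfig
from flockescape.detect import (ManoeuvreRecord, centrality,
                                centroid_trajectory, classify_outcome,
                                detect_splits, label_initiator, main_flock_at,
                                raw_centrality_table, segment_turns,
                                turning_metrics)
from flockescape.fixtures import FixtureSpec, make_fixture


def tracks_from_positions(pos: np.ndarray, hz: float = 5.0) -> pd.DataFrame:
    """Tidy track table from a positions array of shape (T, A, 2)."""
    n_t, n_a = pos.shape[:2]
    times = np.arange(n_t) / hz
    return pd.DataFrame({
        "t_s": np.repeat(times, n_a),
        "agent_id": np.tile(np.arange(n_a), n_t),
        "x_m": pos[:, :, 0].ravel(),
        "y_m": pos[:, :, 1].ravel(),
    })


class TestCentroidTrajectory:
    def test_single_member_identity(self):
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=3, duration_s=10))
        cent = centroid_trajectory(tr, {1})
        own = tr[tr["agent_id"] == 1]
        np.testing.assert_allclose(cent["x_m"], own["x_m"])
        np.testing.assert_allclose(cent["y_m"], own["y_m"])

    def test_mirror_pair_fixed_at_origin(self):
        pos = np.zeros((20, 2, 2))
        t = np.arange(20)
        pos[:, 0] = np.column_stack([t, t])
        pos[:, 1] = -pos[:, 0]
        cent = centroid_trajectory(tracks_from_positions(pos))
        np.testing.assert_allclose(cent[["x_m", "y_m"]], 0.0, atol=1e-12)

    def test_hand_computed_means(self):
        pos = np.array([
            [[0.0, 0.0], [2.0, 0.0], [4.0, 3.0]],
            [[1.0, 1.0], [3.0, 1.0], [5.0, 4.0]],
            [[2.0, 2.0], [4.0, 2.0], [6.0, 5.0]],
        ])
        cent = centroid_trajectory(tracks_from_positions(pos))
        np.testing.assert_allclose(cent["x_m"], [2.0, 3.0, 4.0])
        np.testing.assert_allclose(cent["y_m"], [1.0, 2.0, 3.0])

    def test_empty_members_rejected(self):
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=3, duration_s=5))
        with pytest.raises(ValueError):
            centroid_trajectory(tr, set())


class TestSegmentTurns:
    def test_straight_track_single_straight_segment(self):
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=1, duration_s=30))
        segs = segment_turns(centroid_trajectory(tr))
        assert len(segs) == 1
        assert segs[0].label == "straight"
        assert segs[0].cum_angle == pytest.approx(0.0, abs=0.5)

    @pytest.mark.parametrize("rate, label", [(9.0, "straight"), (12.0, "turn")])
    def test_arc_threshold(self, rate, label):
        tr, _ = make_fixture(FixtureSpec("arc", n_agents=1, duration_s=30,
                                         params={"rate_deg_s": rate}))
        segs = segment_turns(centroid_trajectory(tr))
        assert len(segs) == 1
        assert segs[0].label == label
        assert segs[0].ang_vel == pytest.approx(rate, rel=0.02)

    def test_scripted_turns_recovered(self):
        pieces = [(0.0, 5.0), (40.0, 2.0), (0.0, 5.0), (-60.0, 3.0)]
        tr, _ = make_fixture(FixtureSpec("scripted_turns", n_agents=1,
                                         duration_s=20,
                                         params={"pieces": pieces}))
        segs = segment_turns(centroid_trajectory(tr))
        turns = [s for s in segs if s.label == "turn"]
        assert len(turns) == 2
        assert turns[0].cum_angle == pytest.approx(40.0, abs=2.0)
        assert turns[1].cum_angle == pytest.approx(-60.0, abs=2.0)
        straights = [s for s in segs if s.label == "straight"]
        assert len(straights) == 3

    def test_segments_tile_the_flight(self):
        pieces = [(25.0, 2.0), (0.0, 4.0), (-70.0, 3.0), (0.0, 3.0), (90.0, 4.0)]
        tr, _ = make_fixture(FixtureSpec("scripted_turns", n_agents=1,
                                         duration_s=30,
                                         params={"pieces": pieces}))
        traj = centroid_trajectory(tr)
        segs = segment_turns(traj)
        total = sum(s.duration for s in segs)
        flight = traj["t_s"].max() - traj["t_s"].min()
        assert total == pytest.approx(flight, abs=2 * 0.2)
        for a, b in zip(segs, segs[1:]):
            assert a.t_end == pytest.approx(b.t_start)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"t_s": [0.0, 0.2], "x_m": [0.0, 1.0],
                           "y_m": [0.0, 0.0]})
        with pytest.raises(ValueError):
            segment_turns(df)


class TestTurningMetrics:
    def test_all_straight_flight_is_zero(self):
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=1, duration_s=40))
        segs = segment_turns(centroid_trajectory(tr))
        m = turning_metrics(segs, 40.0)
        assert m == {"turn_rate": 0.0, "time_turning_fraction": 0.0,
                     "angle_per_second": 0.0}

    def test_worked_example(self):
        # one 60 deg turn lasting 4 s in a 40 s flight
        from flockescape.detect import TurnSegment
        segs = [TurnSegment(0.0, 10.0, 1.0, 0.1, "straight"),
                TurnSegment(10.0, 14.0, 60.0, 15.0, "turn"),
                TurnSegment(14.0, 40.0, -2.0, 0.08, "straight")]
        m = turning_metrics(segs, 40.0)
        assert m["turn_rate"] == pytest.approx(0.025)
        assert m["time_turning_fraction"] == pytest.approx(0.10)
        assert m["angle_per_second"] == pytest.approx(1.5)

    def test_continuous_turning_attains_bound(self):
        tr, _ = make_fixture(FixtureSpec("arc", n_agents=1, duration_s=30,
                                         params={"rate_deg_s": 15.0}))
        traj = centroid_trajectory(tr)
        segs = segment_turns(traj)
        flight = traj["t_s"].max() - traj["t_s"].min()
        m = turning_metrics(segs, flight)
        assert m["time_turning_fraction"] == pytest.approx(1.0, abs=0.01)


def brute_force_split_starts(tracks: pd.DataFrame,
                             cfg: DetectConfig) -> set[tuple[int, float]]:
    """Independent reference: per-frame pairwise distances, BFS components,
    literal 10 m / 2 s rule.  Returns {(agent_id, excursion start time)}."""
    times = np.sort(tracks["t_s"].unique())
    agents = np.sort(tracks["agent_id"].unique())
    px = tracks.pivot(index="t_s", columns="agent_id", values="x_m").to_numpy()
    py = tracks.pivot(index="t_s", columns="agent_id", values="y_m").to_numpy()
    frames = np.stack([px, py], axis=-1)
    away = []
    for xy in frames:
        n = len(agents)
        dist = np.array([[np.hypot(*(xy[i] - xy[j])) for j in range(n)]
                         for i in range(n)])
        # BFS connected components under <= split_distance
        comp = [-1] * n
        c = 0
        for s0 in range(n):
            if comp[s0] >= 0:
                continue
            stack = [s0]
            comp[s0] = c
            while stack:
                u = stack.pop()
                for v in range(n):
                    if comp[v] < 0 and dist[u, v] <= cfg.split_distance:
                        comp[v] = c
                        stack.append(v)
            c += 1
        sizes = [comp.count(k) for k in range(c)]
        best = max(sizes)
        tied = [k for k in range(c) if sizes[k] == best]
        main = min(tied, key=lambda k: min(agents[i] for i in range(n)
                                           if comp[i] == k))
        members = [i for i in range(n) if comp[i] == main]
        row = []
        for i in range(n):
            if i in members:
                row.append(False)
            else:
                row.append(min(dist[i, j] for j in members) > cfg.split_distance)
        away.append(row)
    away = np.array(away)
    out = set()
    for i, a in enumerate(agents):
        j = 0
        while j < len(times):
            if away[j, i]:
                k = j
                while k + 1 < len(times) and away[k + 1, i]:
                    k += 1
                if times[k] - times[j] >= cfg.split_min_duration - 1e-9:
                    out.add((int(a), float(times[j])))
                j = k + 1
            else:
                j += 1
    return out


def random_walk_tracks(seed: int, n_agents: int = 10, n_t: int = 60,
                       hz: float = 5.0) -> pd.DataFrame:
    """Random flock-like tracks whose members occasionally wander off."""
    gen = np.random.default_rng(seed)
    pos = np.zeros((n_t, n_agents, 2))
    pos[0] = gen.normal(0, 4, (n_agents, 2))
    drift = gen.normal(0, 1.2, (n_agents, 2))
    for t in range(1, n_t):
        pos[t] = pos[t - 1] + drift / hz + gen.normal(0, 0.6, (n_agents, 2))
    return tracks_from_positions(pos, hz)


class TestDetectSplits:
    def test_cohesive_flock_has_no_events(self):
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=10, duration_s=30))
        assert detect_splits(tr) == []

    def test_single_agent_table_has_no_events(self):
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=1, duration_s=30))
        assert detect_splits(tr) == []

    @pytest.mark.parametrize("excursion_s, expect", [(3.0, 1), (1.5, 0)])
    def test_minimum_duration_rule(self, excursion_s, expect):
        # one bird steps 12 m out laterally for a scripted time, then back
        hz, n_t, n = 5.0, 100, 5
        pos = np.zeros((n_t, n, 2))
        for a in range(n):
            pos[:, a, 1] = 2.0 * a
        pos[:, :, 0] = (np.arange(n_t) / hz * 18.0)[:, None]
        i0 = 40
        k = int(excursion_s * hz)
        pos[i0:i0 + k, n - 1, 1] += 12.0
        ev = detect_splits(tracks_from_positions(pos, hz))
        assert len(ev) == expect
        if expect:
            assert ev[0].kind == "solitary"
            assert ev[0].member_ids == {n - 1}
            assert ev[0].t_start == pytest.approx(i0 / hz)
            assert ev[0].merged_back_at == pytest.approx((i0 + k) / hz)

    def test_joint_departure_is_one_event(self):
        tr, truth = make_fixture(FixtureSpec(
            "subflock_split", n_agents=9, duration_s=30,
            params={"departure_time": 8.0, "bearing_deg": 25.0, "size": 3}))
        ev = detect_splits(tr)
        assert len(ev) == 1
        assert ev[0].size == 3
        assert ev[0].kind == "sub-flock"
        assert ev[0].member_ids == truth.split_events[0].member_ids

    def test_matches_brute_force_oracle_on_random_tracks(self):
        """Every event matches the literal per-frame distance rule: each
        member has exactly one brute-force excursion starting at the event
        (within the simultaneity window), the event is stamped at the
        earliest of them, and no brute-force excursion goes unreported."""
        cfg = DetectConfig()
        for seed in range(100):
            tr = random_walk_tracks(seed)
            expected = brute_force_split_starts(tr, cfg)
            events = detect_splits(tr, cfg)
            claimed = set()
            for ev in events:
                member_starts = []
                for a in ev.member_ids:
                    match = [(aa, s) for (aa, s) in expected - claimed
                             if aa == a and
                             ev.t_start <= s <= ev.t_start + cfg.simultaneity_window]
                    assert match, f"seed {seed}: no oracle excursion for {a}"
                    pick = min(match, key=lambda x: x[1])
                    claimed.add(pick)
                    member_starts.append(pick[1])
                assert ev.t_start == pytest.approx(min(member_starts))
            assert claimed == expected, f"seed {seed}: unreported excursions"

    def test_merge_time_postdates_start(self):
        for seed in range(30):
            for ev in detect_splits(random_walk_tracks(seed + 500)):
                if ev.merged_back_at is not None:
                    assert ev.merged_back_at > ev.t_start


class TestCentrality:
    def test_agent_at_centroid_is_zero(self):
        pos = np.zeros((10, 5, 2))
        for a in range(1, 5):
            ang = 2 * np.pi * (a - 1) / 4
            pos[:, a] = [3 * np.cos(ang), 3 * np.sin(ang)]
        tr = tracks_from_positions(pos)
        assert centrality(tr, 0, 0.0) == pytest.approx(0.0)

    def test_unit_square_corners_are_equal_and_one(self):
        pos = np.zeros((10, 4, 2))
        pos[:, 0] = [0, 0]
        pos[:, 1] = [1, 0]
        pos[:, 2] = [0, 1]
        pos[:, 3] = [1, 1]
        tr = tracks_from_positions(pos)
        raw = raw_centrality_table(tr)
        np.testing.assert_allclose(raw["raw_centrality"], np.sqrt(2) / 2)
        for a in range(4):
            assert centrality(tr, a, 1.0) == pytest.approx(1.0)

    def test_normalization_identity(self):
        tr = random_walk_tracks(3)
        raw = raw_centrality_table(tr)
        norm = raw["raw_centrality"] / raw["raw_centrality"].mean()
        assert norm.mean() == pytest.approx(1.0)


class TestLabelInitiator:
    def test_median_split_of_angular_velocities(self):
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=5, duration_s=20))
        median = 25.0
        labels = []
        for av in (10.0, 20.0, 30.0, 40.0):
            rec = ManoeuvreRecord(0, 2, 5.0, av * 2, 2.0, av, 50.0,
                                  centrality=0.5)
            rec = label_initiator(rec, tr, {"ang_vel": median, "centrality": 1.0})
            labels.append(rec.ang_vel_label)
        assert labels == ["low", "low", "high", "high"]

    def test_centrality_label_median_split(self):
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=5, duration_s=20))
        rec = ManoeuvreRecord(0, 2, 5.0, 40.0, 2.0, 20.0, 50.0, centrality=0.4)
        rec = label_initiator(rec, tr, {"centrality": 1.0, "ang_vel": 20.0})
        assert rec.centrality_label == "central"

    def test_initiator_right_of_centroid_turning_left_is_inwards(self):
        # column flock along y; agent 0 is at the bottom (right of centroid
        # when flying along +x); a left turn (positive) rotates toward it
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=5, duration_s=20))
        rec = ManoeuvreRecord(0, 0, 5.0, 40.0, 2.0, +20.0, 50.0, centrality=1.2)
        rec = label_initiator(rec, tr, {"centrality": 1.0, "ang_vel": 10.0})
        assert rec.direction_label == "inwards"
        rec2 = ManoeuvreRecord(0, 0, 5.0, 40.0, 2.0, -20.0, 50.0, centrality=1.2)
        rec2 = label_initiator(rec2, tr, {"centrality": 1.0, "ang_vel": 10.0})
        assert rec2.direction_label == "outwards"

    def test_degenerate_geometry_defaults_outwards(self):
        pos = np.zeros((20, 3, 2))
        pos[:, 0, 0] = np.arange(20) * 0.2 * 18     # at the centroid track
        pos[:, 1] = pos[:, 0] + [0.0, 4.0]
        pos[:, 2] = pos[:, 0] - [0.0, 4.0]
        tr = tracks_from_positions(pos)
        rec = ManoeuvreRecord(0, 0, 2.0, 40.0, 2.0, 20.0, 50.0, centrality=0.0)
        rec = label_initiator(rec, tr, {"centrality": 1.0, "ang_vel": 10.0})
        assert rec.direction_label == "outwards"


class TestClassifyOutcome:
    def test_unfollowed_departure_is_a_split(self):
        tr, _ = make_fixture(FixtureSpec(
            "solitary_split", n_agents=8, duration_s=30,
            params={"departure_time": 8.0, "bearing_deg": 30.0}))
        rec = ManoeuvreRecord(0, 7, 8.0, 30.0, 1.5, 20.0, 40.0)
        assert classify_outcome(rec, tr) == "split"

    def test_followed_turn_is_collective(self):
        tr, _ = make_fixture(FixtureSpec(
            "follow_all", n_agents=8, duration_s=30,
            params={"turn_time": 10.0, "angle_deg": 60.0, "turn_duration": 2.0}))
        rec = ManoeuvreRecord(0, 3, 10.0, 60.0, 2.0, +30.0, 40.0)
        assert classify_outcome(rec, tr) == "collective_turn"

    def test_wrong_sign_turn_is_not_credited(self):
        tr, _ = make_fixture(FixtureSpec(
            "follow_all", n_agents=8, duration_s=30,
            params={"turn_time": 10.0, "angle_deg": 60.0, "turn_duration": 2.0}))
        rec = ManoeuvreRecord(0, 3, 10.0, 60.0, 2.0, -30.0, 40.0)
        assert classify_outcome(rec, tr) == "none"

    def test_no_pattern_in_window_is_none(self):
        tr, _ = make_fixture(FixtureSpec("straight", n_agents=8, duration_s=30))
        rec = ManoeuvreRecord(0, 3, 10.0, 40.0, 2.0, 20.0, 40.0)
        assert classify_outcome(rec, tr) == "none"

    def test_initiator_outside_main_flock_is_excluded(self):
        tr, _ = make_fixture(FixtureSpec(
            "solitary_split", n_agents=8, duration_s=30,
            params={"departure_time": 5.0, "bearing_deg": 30.0}))
        # manoeuvre starts long after the departure completed
        rec = ManoeuvreRecord(0, 7, 20.0, 30.0, 1.5, 20.0, 40.0)
        assert classify_outcome(rec, tr) == "excluded"

    def test_main_flock_membership(self):
        tr, _ = make_fixture(FixtureSpec(
            "solitary_split", n_agents=8, duration_s=30,
            params={"departure_time": 5.0, "bearing_deg": 30.0}))
        assert main_flock_at(tr, 25.0) == set(range(7))
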