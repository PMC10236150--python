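import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicetrack.detect import Detection
from slicetrack.track import Track, filter_min_length, link, merge_tracks, tracks_to_dataframe


def det(frame, x, y=0.0, label=0, plane=0):
    return Detection(
        frame=frame,
        plane=plane,
        centroid_um=(float(x), float(y)),
        area_um2=50.0,
        pixels=np.array([[0, 0]]),
        label=label,
    )


def make_track(track_id, points):
    """points: iterable of (frame, x, y)."""
    return Track(track_id=track_id, observations=[det(f, x, y) for f, x, y in points])


def obs_key(track):
    return tuple((o.frame, o.x, o.y) for o in track.observations)


class TestTrackType:
    def test_requires_observation(self):
        with pytest.raises(ValueError):
            Track(track_id=0, observations=[])

    def test_frames_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_track(0, [(0, 0, 0), (0, 1, 0)])


class TestLink:
    def test_single_cell_single_track(self):
        dets = [det(f, x=2.0 * f) for f in range(5)]
        tracks = link(dets, max_disp_um=5.0)
        assert len(tracks) == 1
        assert tracks[0].n_observations == 5

    def test_displacement_cap_starts_new_track(self):
        dets = [det(0, 0.0), det(1, 100.0)]
        tracks = link(dets, max_disp_um=5.0)
        assert len(tracks) == 2

    def test_crossing_cells_no_swap(self):
        # cross in x, but stay 6 um apart in y; max_disp 5 forbids swapping
        dets = []
        for f in range(11):
            dets.append(det(f, x=2.0 * f, y=0.0, label=0))
            dets.append(det(f, x=20.0 - 2.0 * f, y=6.0, label=1))
        tracks = link(dets, max_disp_um=5.0)
        assert len(tracks) == 2
        for t in tracks:
            ys = {o.y for o in t.observations}
            assert len(ys) == 1  # no identity swap across the crossing

    def test_matches_brute_force_assignment(self):
        # 3 cells, optimal global assignment verified against exhaustion
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 100, size=(3, 2))
        dets, truth = [], {i: [] for i in range(3)}
        for f in range(6):
            for i in range(3):
                d = det(f, pos[i, 0], pos[i, 1], label=i)
                dets.append(d)
                truth[i].append((f, d.x, d.y))
            pos = pos + rng.uniform(-1.5, 1.5, size=(3, 2))
            # brute-force check that identity assignment is optimal per frame
        tracks = link(dets, max_disp_um=6.0)
        assert sorted(obs_key(t) for t in tracks) == sorted(tuple(v) for v in truth.values())

    def test_memory_bridges_single_frame_gap(self):
        dets = [det(0, 0.0), det(1, 1.0), det(3, 3.0), det(4, 4.0)]
        tracks = link(dets, max_disp_um=5.0, memory=1)
        assert len(tracks) == 1
        assert list(tracks[0].frames) == [0, 1, 3, 4]

    def test_no_memory_fragments(self):
        dets = [det(0, 0.0), det(1, 1.0), det(3, 3.0)]
        tracks = link(dets, max_disp_um=5.0, memory=0)
        assert len(tracks) == 2

    def test_bad_params(self):
        with pytest.raises(ValueError):
            link([], max_disp_um=0.0)
        with pytest.raises(ValueError):
            link([], max_disp_um=1.0, memory=-1)


class TestMergeTracks:
    def test_merges_close_in_space_and_time(self):
        a = make_track(0, [(f, 0.0, 0.0) for f in range(8, 11)])
        b = make_track(1, [(11, 5.0, 0.0), (12, 5.0, 0.0)])
        merged = merge_tracks([a, b])
        assert len(merged) == 1
        assert merged[0].n_observations == 5
        assert merged[0].merged_from == [0, 1]

    def test_distance_boundary_10um_not_merged(self):
        a = make_track(0, [(10, 0.0, 0.0)])
        b = make_track(1, [(11, 12.0, 0.0)])
        assert len(merge_tracks([a, b])) == 2
        # exactly 10 um is also not merged (strict <)
        c = make_track(2, [(11, 10.0, 0.0)])
        assert len(merge_tracks([a, c])) == 2

    def test_frame_gap_boundary_2_not_merged(self):
        a = make_track(0, [(10, 0.0, 0.0)])
        b = make_track(1, [(12, 5.0, 0.0)])
        assert len(merge_tracks([a, b])) == 2

    def test_nearest_candidate_wins(self):
        a = make_track(0, [(10, 0.0, 0.0)])
        near = make_track(1, [(11, 2.0, 0.0)])
        far = make_track(2, [(11, 6.0, 0.0)])
        merged = merge_tracks([a, near, far])
        by_obs = {obs_key(t): t for t in merged}
        assert ((10, 0.0, 0.0), (11, 2.0, 0.0)) in by_obs

    def test_overlapping_tracks_never_merged(self):
        a = make_track(0, [(0, 0.0, 0.0), (5, 1.0, 0.0)])
        b = make_track(1, [(3, 1.0, 0.0), (6, 2.0, 0.0)])
        assert len(merge_tracks([a, b])) == 2

    def test_observation_count_conserved(self):
        rng = np.random.default_rng(1)
        tracks = []
        f = 0
        for i in range(12):
            n = int(rng.integers(1, 5))
            tracks.append(make_track(i, [(f + k, float(rng.uniform(0, 30)), 0.0) for k in range(n)]))
            f += n + int(rng.integers(0, 2))
        merged = merge_tracks(tracks)
        assert sum(t.n_observations for t in merged) == sum(t.n_observations for t in tracks)

    def test_idempotent_at_fixpoint(self):
        a = make_track(0, [(0, 0.0, 0.0), (1, 1.0, 0.0)])
        b = make_track(1, [(2, 2.0, 0.0), (3, 3.0, 0.0)])
        once = merge_tracks([a, b])
        twice = merge_tracks(once)
        assert sorted(obs_key(t) for t in twice) == sorted(obs_key(t) for t in once)

    def test_chained_merge_reaches_fixpoint(self):
        fragments = [make_track(i, [(2 * i, float(i), 0.0), (2 * i + 1, float(i), 0.0)]) for i in range(4)]
        merged = merge_tracks(fragments)
        assert len(merged) == 1
        assert merged[0].n_observations == 8


def brute_force_merge(tracks, dist_thresh=10.0, gap_thresh=2):
    """Independent all-pairs oracle: repeatedly merge the globally closest
    eligible (end, start) pair until none remains."""
    pool = [(t.track_id, list(t.observations)) for t in tracks]
    while True:
        candidates = []
        for (ia, obs_a), (ib, obs_b) in itertools.permutations(pool, 2):
            gap = obs_b[0].frame - obs_a[-1].frame
            if 0 < gap < gap_thresh:
                d = np.hypot(obs_a[-1].x - obs_b[0].x, obs_a[-1].y - obs_b[0].y)
                if d < dist_thresh:
                    candidates.append((d, gap, ia, ib))
        if not candidates:
            break
        _, _, ia, ib = min(candidates)
        obs_a = next(o for i, o in pool if i == ia)
        obs_b = next(o for i, o in pool if i == ib)
        pool = [(i, o) for i, o in pool if i not in (ia, ib)]
        pool.append((min(ia, ib), obs_a + obs_b))
    return sorted(tuple((o.frame, o.x, o.y) for o in obs) for _, obs in pool)


class TestMergeOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        tracks = []
        for i in range(int(rng.integers(5, 20))):
            start = int(rng.integers(0, 15))
            n = int(rng.integers(1, 4))
            x0, y0 = rng.uniform(0, 40, 2)
            tracks.append(
                make_track(i, [(start + k, float(x0 + k), float(y0)) for k in range(n)])
            )
        result = sorted(obs_key(t) for t in merge_tracks(tracks))
        assert result == brute_force_merge(tracks)


class TestFilterMinLength:
    def test_six_kept_five_dropped(self):
        six = make_track(0, [(f, 0.0, 0.0) for f in range(6)])
        five = make_track(1, [(f, 20.0, 0.0) for f in range(5)])
        kept = filter_min_length([six, five], min_frames=6)
        assert kept == [six]

    def test_merge_before_filter_keeps_joined_fragments(self):
        a = make_track(0, [(f, 0.0, 0.0) for f in range(3)])
        b = make_track(1, [(f, 2.0, 0.0) for f in range(3, 6)])
        kept = filter_min_length(merge_tracks([a, b]), min_frames=6)
        assert len(kept) == 1
        assert kept[0].n_observations == 6


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 10), st.floats(0, 30), st.floats(0, 30)), min_size=2, max_size=30))
def test_merge_conserves_observations_property(points):
    tracks = []
    for i, (f, x, y) in enumerate(points):
        tracks.append(make_track(i, [(f, float(np.round(x, 3)), float(np.round(y, 3)))]))
    merged = merge_tracks(tracks)
    total = sum(t.n_observations for t in merged)
    assert total == len(points)
    for t in merged:
        assert np.all(np.diff(t.frames) > 0)


def test_tracks_dataframe_roundtrip_columns():
    t = make_track(3, [(0, 1.0, 2.0), (1, 3.0, 4.0)])
    df = tracks_to_dataframe([t])
    assert list(df.columns) == ["track_id", "frame", "plane", "x_um", "y_um", "area_um2"]
    assert len(df) == 2
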