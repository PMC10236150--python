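import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicetrack.detect import Detection
from slicetrack.image_io import RegionMaskSet
from slicetrack.metrics import (
    TrackMetrics,
    classify_localization,
    compute_track_metrics,
    dwell_and_entry,
    metrics_to_dataframe,
    metrics_to_tidy,
    momentary_speed,
    summarize_acquisition,
)
from slicetrack.track import Track


def det(frame, x, y=0.0, plane=0, pixels=None):
    if pixels is None:
        pixels = np.array([[int(y), int(x)]])
    return Detection(
        frame=frame,
        plane=plane,
        centroid_um=(float(x), float(y)),
        area_um2=float(len(pixels)),
        pixels=np.asarray(pixels),
        label=0,
    )


def make_track(points, track_id=0, plane=0, pixels_per_point=None):
    obs = []
    for i, (f, x, y) in enumerate(points):
        px = pixels_per_point[i] if pixels_per_point is not None else None
        obs.append(det(f, x, y, plane=plane, pixels=px))
    return Track(track_id=track_id, observations=obs)


def half_ecm_masks(n_planes=1, size=40):
    """ECM on the left half (cols < size//2), tumor on the right."""
    ecm = np.zeros((n_planes, size, size), dtype=bool)
    ecm[:, :, : size // 2] = True
    return RegionMaskSet(ecm)


class TestMomentarySpeed:
    def test_stationary_zero(self):
        track = make_track([(f, 5.0, 5.0) for f in range(4)])
        assert np.allclose(momentary_speed(track, 30.0), 0.0)

    def test_five_um_in_30s_is_10_um_per_min(self):
        track = make_track([(0, 0.0, 0.0), (1, 5.0, 0.0)])
        assert momentary_speed(track, 30.0) == pytest.approx([10.0])

    def test_gap_uses_elapsed_time(self):
        track = make_track([(0, 0.0, 0.0), (2, 5.0, 0.0)])  # 1-frame gap -> 60 s
        assert momentary_speed(track, 30.0) == pytest.approx([5.0])

    def test_single_observation_empty(self):
        track = make_track([(0, 0.0, 0.0)])
        assert len(momentary_speed(track, 30.0)) == 0

    def test_translation_invariance_scaling_equivariance(self):
        pts = [(0, 1.0, 2.0), (1, 4.0, 6.0), (2, 2.0, 3.0)]
        base = momentary_speed(make_track(pts), 30.0)
        shifted = momentary_speed(make_track([(f, x + 7.0, y - 3.0) for f, x, y in pts]), 30.0)
        scaled = momentary_speed(make_track([(f, 2 * x, 2 * y) for f, x, y in pts]), 30.0)
        assert np.allclose(shifted, base)
        assert np.allclose(scaled, 2 * base)


class TestClassifyLocalization:
    def test_fully_inside_tumor(self):
        masks = half_ecm_masks()
        track = make_track([(0, 30.0, 10.0)], pixels_per_point=[np.array([[10, 30], [10, 31]])])
        assert classify_localization(track, masks) == ["tumor"]

    def test_single_overlapping_pixel_is_ecm(self):
        masks = half_ecm_masks()
        # one pixel at col 19 (ECM), rest in tumor
        px = np.array([[10, 19], [10, 30], [10, 31]])
        track = make_track([(0, 30.0, 10.0)], pixels_per_point=[px])
        assert classify_localization(track, masks) == ["ecm"]

    def test_all_ecm_mask_degenerate(self):
        masks = RegionMaskSet(np.ones((1, 40, 40), dtype=bool))
        track = make_track([(0, 30.0, 10.0), (1, 31.0, 10.0)])
        assert classify_localization(track, masks) == ["ecm", "ecm"]

    def test_plane_out_of_range_raises(self):
        masks = half_ecm_masks(n_planes=1)
        track = make_track([(0, 30.0, 10.0)], plane=3)
        with pytest.raises(ValueError, match="plane"):
            classify_localization(track, masks)

    def test_uses_own_plane_mask(self):
        ecm = np.zeros((2, 40, 40), dtype=bool)
        ecm[1] = True  # plane 1 fully ECM, plane 0 fully tumor
        masks = RegionMaskSet(ecm)
        t0 = make_track([(0, 10.0, 10.0)], plane=0)
        t1 = make_track([(0, 10.0, 10.0)], plane=1)
        assert classify_localization(t0, masks) == ["tumor"]
        assert classify_localization(t1, masks) == ["ecm"]


class TestDwellAndEntry:
    def test_half_dwell_is_high(self):
        labels = ["tumor"] * 5 + ["ecm"] * 5
        dwell, entered, high = dwell_and_entry(labels)
        assert dwell == 0.5
        assert entered is True
        assert high is True  # "at least 50%" boundary

    def test_never_in_tumor(self):
        dwell, entered, high = dwell_and_entry(["ecm"] * 4)
        assert (dwell, entered, high) == (0.0, False, False)

    def test_always_in_tumor(self):
        dwell, entered, high = dwell_and_entry(["tumor"] * 3)
        assert (dwell, entered, high) == (1.0, True, True)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dwell_and_entry([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from(["tumor", "ecm"]), min_size=1, max_size=40))
    def test_counts_partition_observations(self, labels):
        dwell, entered, high = dwell_and_entry(labels)
        n_tumor = round(dwell * len(labels))
        assert n_tumor + labels.count("ecm") == len(labels)
        assert high == (dwell >= 0.5)
        assert entered == (n_tumor >= 1)


class TestComputeTrackMetrics:
    def test_step_attributed_to_first_observation_region(self):
        masks = half_ecm_masks()
        # obs0 in ECM (col 5), obs1 in tumor (col 30): step belongs to ECM
        track = make_track([(0, 5.0, 10.0), (1, 30.0, 10.0)])
        m = compute_track_metrics(track, masks, 30.0)
        assert m.region_per_frame == ["ecm", "tumor"]
        assert np.isnan(m.mean_speed_tumor)
        assert m.mean_speed_ecm == pytest.approx(50.0)

    def test_speed_count_invariant(self):
        masks = half_ecm_masks()
        track = make_track([(f, 5.0 + f, 10.0) for f in range(5)])
        m = compute_track_metrics(track, masks, 30.0)
        assert len(m.momentary_speeds) == len(m.region_per_frame) - 1

    def test_invariant_validation(self):
        with pytest.raises(ValueError, match="high_dwell"):
            TrackMetrics(
                track_id=0,
                momentary_speeds=np.array([1.0]),
                region_per_frame=["tumor", "tumor"],
                dwell_fraction=1.0,
                entered_tumor=True,
                high_dwell=False,
                mean_speed=1.0,
                mean_speed_tumor=1.0,
                mean_speed_ecm=float("nan"),
            )


class TestSummarizeAcquisition:
    def _metrics(self, regions_list):
        masks = half_ecm_masks()
        out = []
        for i, cols in enumerate(regions_list):
            track = make_track([(f, float(c), 10.0) for f, c in enumerate(cols)], track_id=i)
            out.append(compute_track_metrics(track, masks, 30.0))
        return out

    def test_pct_entered_forced_arithmetic(self):
        # 4 tracks, exactly one ever in the tumor half (col >= 20)
        metrics = self._metrics([[5, 6], [7, 8], [9, 10], [5, 30]])
        summary = summarize_acquisition(metrics)
        assert summary.n_tracks == 4
        assert summary.pct_entered_tumor == 25.0

    def test_outliers_off_by_default(self):
        metrics = self._metrics([[5, 6], [7, 8]])
        assert summarize_acquisition(metrics).outlier_removed_ids == []

    def test_mad_outlier_removal_flags_extreme_track(self):
        cols = [[5.0, 5.5 + 0.1 * i] for i in range(10)]
        cols.append([5.0, 19.0])  # absurdly fast track
        metrics = self._metrics(cols)
        summary = summarize_acquisition(metrics, outlier_policy="mad")
        assert summary.outlier_removed_ids == [10]

    def test_empty_compartment_absent_not_zero(self):
        metrics = self._metrics([[5, 6], [7, 8]])  # never in tumor
        summary = summarize_acquisition(metrics)
        assert len(summary.track_mean_speeds_tumor) == 0
        assert np.isnan(summary.mean_speed_tumor)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_acquisition([])

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            summarize_acquisition(self._metrics([[5, 6]]), outlier_policy="rout")


def test_dataframe_outputs():
    masks = half_ecm_masks()
    track = make_track([(0, 5.0, 10.0), (1, 6.0, 10.0), (2, 30.0, 10.0)])
    m = compute_track_metrics(track, masks, 30.0)
    wide = metrics_to_dataframe([m])
    tidy = metrics_to_tidy([m])
    assert len(wide) == 1
    assert len(tidy) == 2
    assert set(tidy["region"]) <= {"tumor", "ecm"}
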