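"""Motility metrics: momentary speed, tumor/ECM localization, dwell fractions.

Localization follows the strict pixel-overlap rule: a cell is
tumor-localized in a frame only if *no* pixel of its segmentation mask
overlaps the ECM mask of its own plane.  A cell has high tumor dwell when
it spends at least 50% of its observed frames tumor-localized (the
``>= 0.5`` boundary is pinned by tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from slicetrack.image_io import RegionMaskSet
from slicetrack.track import Track

__all__ = [
    "TrackMetrics",
    "AcquisitionSummary",
    "momentary_speed",
    "classify_localization",
    "dwell_and_entry",
    "compute_track_metrics",
    "summarize_acquisition",
    "metrics_to_dataframe",
    "metrics_to_tidy",
]


@dataclass
class TrackMetrics:
    track_id: int
    momentary_speeds: np.ndarray  # um/min, one per successive observation pair
    region_per_frame: list[str]  # 'tumor' / 'ecm', one per observation
    dwell_fraction: float
    entered_tumor: bool
    high_dwell: bool
    mean_speed: float
    mean_speed_tumor: float  # NaN when the track has no step starting in tumor
    mean_speed_ecm: float

    def __post_init__(self) -> None:
        self.momentary_speeds = np.asarray(self.momentary_speeds, dtype=float)
        if len(self.momentary_speeds) != len(self.region_per_frame) - 1:
            raise ValueError("need exactly one speed per successive observation pair")
        if not 0.0 <= self.dwell_fraction <= 1.0:
            raise ValueError("dwell_fraction must lie in [0, 1]")
        if self.high_dwell != (self.dwell_fraction >= 0.5):
            raise ValueError("high_dwell must equal (dwell_fraction >= 0.5)")


@dataclass
class AcquisitionSummary:
    n_tracks: int
    pct_entered_tumor: float
    pct_high_dwell: float
    track_mean_speeds_tumor: np.ndarray  # per-track means, tracks with tumor steps
    track_mean_speeds_ecm: np.ndarray
    pooled_speeds_tumor: np.ndarray  # all momentary speeds, pooled
    pooled_speeds_ecm: np.ndarray
    outlier_removed_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_entered_tumor <= 100.0:
            raise ValueError("pct_entered_tumor must lie in [0, 100]")
        if not 0.0 <= self.pct_high_dwell <= 100.0:
            raise ValueError("pct_high_dwell must lie in [0, 100]")

    @property
    def mean_speed_tumor(self) -> float:
        arr = self.track_mean_speeds_tumor
        return float(np.mean(arr)) if len(arr) else float("nan")

    @property
    def mean_speed_ecm(self) -> float:
        arr = self.track_mean_speeds_ecm
        return float(np.mean(arr)) if len(arr) else float("nan")


def momentary_speed(track: Track, frame_interval_s: float) -> np.ndarray:
    """Speeds (um/min) between successive observations of one track.

    The distance travelled between two successive observations is divided by
    the actual elapsed time, so a 1-frame gap uses twice the frame interval.
    Single-observation tracks yield an empty array.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    if track.n_observations < 2:
        return np.empty(0)
    pos = track.positions_um()
    frames = track.frames
    dist = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    elapsed_min = np.diff(frames) * frame_interval_s / 60.0
    return dist / elapsed_min


def classify_localization(track: Track, masks: RegionMaskSet) -> list[str]:
    """Label each observation 'tumor' or 'ecm' by the pixel-overlap rule.

    An observation is tumor-localized iff no pixel of its segmentation mask
    overlaps the ECM mask of the observation's own plane; a single
    overlapping pixel classifies the frame as 'ecm'.
    """
    labels = []
    for obs in track.observations:
        if not 0 <= obs.plane < masks.n_planes:
            raise ValueError(
                f"observation plane {obs.plane} outside mask set with {masks.n_planes} planes"
            )
        ecm = masks.ecm[obs.plane]
        rows, cols = obs.pixels[:, 0], obs.pixels[:, 1]
        inside = (rows >= 0) & (rows < ecm.shape[0]) & (cols >= 0) & (cols < ecm.shape[1])
        overlap = np.any(ecm[rows[inside], cols[inside]])
        labels.append("ecm" if overlap else "tumor")
    return labels


def dwell_and_entry(region_per_frame: list[str]) -> tuple[float, bool, bool]:
    """(dwell_fraction, entered_tumor, high_dwell) from per-frame region labels."""
    if not region_per_frame:
        raise ValueError("region_per_frame must be non-empty")
    n_tumor = sum(1 for r in region_per_frame if r == "tumor")
    dwell = n_tumor / len(region_per_frame)
    return dwell, n_tumor >= 1, dwell >= 0.5


def compute_track_metrics(
    track: Track, masks: RegionMaskSet, frame_interval_s: float
) -> TrackMetrics:
    """Full per-track metrics: speeds, localization, dwell and flags.

    Each step between two observations is attributed to the region of its
    first observation.
    """
    speeds = momentary_speed(track, frame_interval_s)
    regions = classify_localization(track, masks)
    dwell, entered, high = dwell_and_entry(regions)
    step_regions = np.array(regions[:-1]) if len(regions) > 1 else np.empty(0, dtype="U5")
    tumor_speeds = speeds[step_regions == "tumor"] if len(speeds) else np.empty(0)
    ecm_speeds = speeds[step_regions == "ecm"] if len(speeds) else np.empty(0)
    return TrackMetrics(
        track_id=track.track_id,
        momentary_speeds=speeds,
        region_per_frame=regions,
        dwell_fraction=dwell,
        entered_tumor=entered,
        high_dwell=high,
        mean_speed=float(np.mean(speeds)) if len(speeds) else float("nan"),
        mean_speed_tumor=float(np.mean(tumor_speeds)) if len(tumor_speeds) else float("nan"),
        mean_speed_ecm=float(np.mean(ecm_speeds)) if len(ecm_speeds) else float("nan"),
    )


def _mad_outliers(values: np.ndarray, q: float) -> np.ndarray:
    """Robust two-sided outlier flags at nominal false-discovery level ``q``.

    Approximates Prism's ROUT procedure with a median/MAD robust z-score and
    a normal-quantile cutoff at q/2 per tail; this is a documented
    approximation, not a reimplementation of ROUT.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = stats.median_abs_deviation(values, scale="normal")
    if mad == 0:
        return np.zeros(len(values), dtype=bool)
    z = np.abs(values - med) / mad
    return z > stats.norm.isf(q / 2)


def summarize_acquisition(
    track_metrics: list[TrackMetrics],
    outlier_policy: str = "none",
    outlier_q: float = 0.02,
) -> AcquisitionSummary:
    """Pool per-track metrics into an acquisition-level summary.

    ``outlier_policy`` is ``"none"`` (default) or ``"mad"`` (robust MAD
    outlier removal on per-track mean speeds at nominal level ``outlier_q``).
    Empty compartments yield empty speed arrays (NaN means), never zeros.
    """
    if not track_metrics:
        raise ValueError("need at least one track")
    if outlier_policy not in ("none", "mad"):
        raise ValueError(f"unknown outlier_policy {outlier_policy!r}")

    removed_ids: list[int] = []
    kept = list(track_metrics)
    if outlier_policy == "mad":
        means = np.array([m.mean_speed for m in kept])
        usable = ~np.isnan(means)
        flags = np.zeros(len(kept), dtype=bool)
        if usable.sum() >= 3:
            flags[usable] = _mad_outliers(means[usable], outlier_q)
        removed_ids = [m.track_id for m, f in zip(kept, flags) if f]
        kept = [m for m, f in zip(kept, flags) if not f]

    n = len(track_metrics)
    n_entered = sum(m.entered_tumor for m in kept)
    n_high = sum(m.high_dwell for m in kept)
    denom = len(kept) if kept else 1
    return AcquisitionSummary(
        n_tracks=n,
        pct_entered_tumor=100.0 * n_entered / denom,
        pct_high_dwell=100.0 * n_high / denom,
        track_mean_speeds_tumor=np.array(
            [m.mean_speed_tumor for m in kept if not np.isnan(m.mean_speed_tumor)]
        ),
        track_mean_speeds_ecm=np.array(
            [m.mean_speed_ecm for m in kept if not np.isnan(m.mean_speed_ecm)]
        ),
        pooled_speeds_tumor=np.concatenate(
            [
                m.momentary_speeds[np.array(m.region_per_frame[:-1]) == "tumor"]
                for m in kept
                if len(m.momentary_speeds)
            ]
            or [np.empty(0)]
        ),
        pooled_speeds_ecm=np.concatenate(
            [
                m.momentary_speeds[np.array(m.region_per_frame[:-1]) == "ecm"]
                for m in kept
                if len(m.momentary_speeds)
            ]
            or [np.empty(0)]
        ),
        outlier_removed_ids=removed_ids,
    )


def metrics_to_dataframe(track_metrics: list[TrackMetrics]) -> pd.DataFrame:
    """One row per track."""
    return pd.DataFrame(
        {
            "track_id": [m.track_id for m in track_metrics],
            "n_observations": [len(m.region_per_frame) for m in track_metrics],
            "dwell_fraction": [m.dwell_fraction for m in track_metrics],
            "entered_tumor": [m.entered_tumor for m in track_metrics],
            "high_dwell": [m.high_dwell for m in track_metrics],
            "mean_speed": [m.mean_speed for m in track_metrics],
            "mean_speed_tumor": [m.mean_speed_tumor for m in track_metrics],
            "mean_speed_ecm": [m.mean_speed_ecm for m in track_metrics],
        }
    )


def metrics_to_tidy(track_metrics: list[TrackMetrics]) -> pd.DataFrame:
    """Long format: one row per momentary speed, for external stats tools."""
    rows = []
    for m in track_metrics:
        for k, speed in enumerate(m.momentary_speeds):
            rows.append(
                {
                    "track_id": m.track_id,
                    "step": k,
                    "region": m.region_per_frame[k],
                    "speed_um_per_min": speed,
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "step", "region", "speed_um_per_min"])
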