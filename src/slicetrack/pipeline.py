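"""End-to-end analysis pipelines composing the processing stages.

Slice pipeline order is fixed and recorded in provenance:
drift -> region masks -> bleed/background correction -> detection ->
Z-collapse -> linking -> merging -> length filter -> metrics -> summary.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import skimage

import slicetrack
from slicetrack import detect, matrigel, metrics, preprocess, track
from slicetrack.image_io import ImageStack, RegionMaskSet, VolumeStack, derive_region_masks

__all__ = ["run_slice_pipeline", "run_matrigel_pipeline", "provenance_header"]


def provenance_header() -> dict[str, str]:
    return {
        "slicetrack": slicetrack.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
    }


def run_slice_pipeline(
    stack: ImageStack,
    masks: RegionMaskSet | None = None,
    *,
    correct_drift: bool = True,
    bleed_coeff: float | None = None,
    median_radius: int = 1,
    threshold_method: str = "otsu",
    nominal_cell_radius_um: float = 5.0,
    min_area_um2: float | None = None,
    max_area_um2: float | None = None,
    match_radius_um: float | None = None,
    max_disp_um: float | None = None,
    memory: int = 1,
    merge_dist_um: float = 10.0,
    merge_frame_gap: int = 2,
    min_frames: int = 6,
    outlier_policy: str = "none",
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the full slice-migration analysis on a calibrated stack.

    Size bounds default to [0.25x, 2.5x] of the nominal cell area implied by
    ``nominal_cell_radius_um``; the Z-collapse match radius defaults to one
    cell radius; ``max_disp_um`` defaults to 3x the nominal per-frame step of
    a 6 um/min cell.  Returns a dict of result tables, the summary, and a
    provenance record of every effective parameter.
    """
    nominal_area = np.pi * nominal_cell_radius_um**2
    if min_area_um2 is None:
        min_area_um2 = 0.25 * nominal_area
    if max_area_um2 is None:
        max_area_um2 = 2.5 * nominal_area
    if match_radius_um is None:
        match_radius_um = nominal_cell_radius_um
    if max_disp_um is None:
        max_disp_um = 3.0 * 6.0 * stack.frame_interval / 60.0

    # 1. drift correction, estimated on the ECM channel
    if correct_drift and stack.n_frames >= 2:
        ecm_proj = stack.channel("ecm").mean(axis=1)  # (T, Y, X)
        drift = preprocess.estimate_drift(ecm_proj)
        stack = preprocess.apply_drift(stack, drift)
    else:
        drift = preprocess.DriftModel(
            shifts=np.zeros((stack.n_frames, 2)), residuals=np.zeros(stack.n_frames)
        )

    # 2. region masks (in the corrected frame)
    if masks is None:
        masks = derive_region_masks(stack)
    elif masks.shape_yx != stack.shape_yx or masks.n_planes != stack.n_planes:
        raise ValueError("supplied region masks do not match the stack geometry")

    # 3. bleed-through/background correction + smoothing of the cell channel
    corrected = preprocess.correct_cell_channel(
        stack.channel("cell"), stack.channel("ecm"), bleed_coeff=bleed_coeff, median_radius=median_radius
    )

    # 4-5. per-frame/plane segmentation, size filter, Z-collapse
    removed = {"removed_small": 0, "removed_large": 0}
    all_dets: list[detect.Detection] = []
    for t in range(stack.n_frames):
        frame_dets: list[detect.Detection] = []
        for z in range(stack.n_planes):
            frame_dets.extend(
                detect.segment_frame(
                    corrected[t, z],
                    stack.pixel_size_xy,
                    frame=t,
                    plane=z,
                    threshold_method=threshold_method,
                    valid=stack.valid[t] if stack.valid is not None else None,
                )
            )
        frame_dets, counts = detect.filter_by_size(frame_dets, min_area_um2, max_area_um2)
        removed["removed_small"] += counts["removed_small"]
        removed["removed_large"] += counts["removed_large"]
        all_dets.extend(detect.collapse_z(frame_dets, match_radius_um))

    # 6-8. link, merge, length filter
    tracks = track.link(all_dets, max_disp_um=max_disp_um, memory=memory)
    tracks = track.merge_tracks(tracks, dist_thresh_um=merge_dist_um, frame_gap_thresh=merge_frame_gap)
    tracks = track.filter_min_length(tracks, min_frames=min_frames)

    # 9-10. metrics and summary
    track_metrics = [
        metrics.compute_track_metrics(t, masks, stack.frame_interval) for t in tracks
    ]
    summary = (
        metrics.summarize_acquisition(track_metrics, outlier_policy=outlier_policy)
        if track_metrics
        else None
    )

    provenance = {
        "stage_order": [
            "drift",
            "region_masks",
            "bleed_background_median",
            "segment",
            "size_filter",
            "collapse_z",
            "link",
            "merge",
            "min_length_filter",
            "metrics",
            "summary",
        ],
        "parameters": {
            "correct_drift": correct_drift,
            "bleed_coeff": bleed_coeff,
            "median_radius": median_radius,
            "threshold_method": threshold_method,
            "min_area_um2": min_area_um2,
            "max_area_um2": max_area_um2,
            "match_radius_um": match_radius_um,
            "max_disp_um": max_disp_um,
            "memory": memory,
            "merge_dist_um": merge_dist_um,
            "merge_frame_gap": merge_frame_gap,
            "min_frames": min_frames,
            "outlier_policy": outlier_policy,
            "mask_source": masks.source,
            "size_filter_removed": removed,
        },
        "calibration": {
            "pixel_size_xy": stack.pixel_size_xy,
            "z_spacing": stack.z_spacing,
            "frame_interval": stack.frame_interval,
        },
        "versions": provenance_header(),
    }

    tracks_df = track.tracks_to_dataframe(tracks)
    metrics_df = metrics.metrics_to_dataframe(track_metrics)
    summary_df = pd.DataFrame(
        [
            {
                "n_tracks": summary.n_tracks,
                "pct_entered_tumor": summary.pct_entered_tumor,
                "pct_high_dwell": summary.pct_high_dwell,
                "mean_speed_tumor": summary.mean_speed_tumor,
                "mean_speed_ecm": summary.mean_speed_ecm,
                "n_outliers_removed": len(summary.outlier_removed_ids),
            }
        ]
        if summary is not None
        else []
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        drift.to_csv(out_dir / "drift.csv")
        tracks_df.to_csv(out_dir / "tracks.csv", index=False)
        metrics_df.to_csv(out_dir / "track_metrics.csv", index=False)
        summary_df.to_csv(out_dir / "summary.csv", index=False)
        metrics.metrics_to_tidy(track_metrics).to_csv(out_dir / "speeds_tidy.csv", index=False)
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return {
        "drift": drift,
        "masks": masks,
        "tracks": tracks,
        "track_metrics": track_metrics,
        "summary": summary,
        "tracks_df": tracks_df,
        "metrics_df": metrics_df,
        "summary_df": summary_df,
        "provenance": provenance,
    }


def run_matrigel_pipeline(
    volume: VolumeStack,
    *,
    threshold_method: str = "otsu",
    seed_min_distance_um: float = 4.0,
    thresholds_um: tuple[float, ...] = (10.0, 100.0),
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Segment a Matrigel Z-stack and quantify invasion distances."""
    labels = matrigel.segment_nuclei_3d(
        volume, threshold_method=threshold_method, seed_min_distance_um=seed_min_distance_um
    )
    n_cells = int(labels.max())
    if n_cells > 0:
        result = matrigel.invasion_distances(labels, volume)
        fractions = matrigel.fraction_beyond(result, thresholds_um)
        cells_df = result.to_dataframe()
        summary_df = pd.DataFrame(
            [
                {
                    "n_cells": result.n_cells,
                    "baseline_z_um": result.baseline_z_um,
                    **{f"fraction_beyond_{t:g}um": f for t, f in fractions.items()},
                }
            ]
        )
    else:
        result = None
        fractions = {float(t): float("nan") for t in thresholds_um}
        cells_df = pd.DataFrame(columns=["label", "x_um", "y_um", "z_um", "distance_um"])
        summary_df = pd.DataFrame(
            [
                {
                    "n_cells": 0,
                    "baseline_z_um": float("nan"),
                    **{f"fraction_beyond_{t:g}um": float("nan") for t in thresholds_um},
                }
            ]
        )

    provenance = {
        "stage_order": ["segment_nuclei_3d", "invasion_distances", "fraction_beyond"],
        "parameters": {
            "threshold_method": threshold_method,
            "seed_min_distance_um": seed_min_distance_um,
            "thresholds_um": list(thresholds_um),
        },
        "calibration": {"pixel_size_xy": volume.pixel_size_xy, "z_spacing": volume.z_spacing},
        "versions": provenance_header(),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cells_df.to_csv(out_dir / "cells.csv", index=False)
        summary_df.to_csv(out_dir / "summary.csv", index=False)
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return {
        "labels": labels,
        "result": result,
        "fractions": fractions,
        "cells_df": cells_df,
        "summary_df": summary_df,
        "provenance": provenance,
    }
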