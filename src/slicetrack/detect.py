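"""Per-frame cell segmentation, size filtering and Z-collapse."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure

__all__ = ["Detection", "segment_frame", "filter_by_size", "collapse_z", "detections_to_dataframe"]


@dataclass
class Detection:
    """One segmented cell in one frame and plane.

    ``centroid_um`` is ``(x, y)`` in micrometers (pixel-center convention);
    ``pixels`` is an ``(n, 2)`` array of ``(row, col)`` indices.
    """

    frame: int
    plane: int
    centroid_um: tuple[float, float]
    area_um2: float
    pixels: np.ndarray
    label: int
    total_intensity: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) array of (row, col)")

    @property
    def x(self) -> float:
        return self.centroid_um[0]

    @property
    def y(self) -> float:
        return self.centroid_um[1]

    def distance_to(self, other: "Detection") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))


def segment_frame(
    image: np.ndarray,
    pixel_size_xy: float,
    frame: int = 0,
    plane: int = 0,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    weighted_centroid: bool = False,
    valid: np.ndarray | None = None,
) -> list[Detection]:
    """Segment cells in one preprocessed 2D image by intensity thresholding.

    Connected components above the threshold become detections with binary
    (default) or intensity-weighted centroids.  A threshold above the image
    maximum yields an empty result with a warning, not an error.
    """
    image = np.asarray(image, dtype=float)
    if threshold_method == "otsu":
        if image.max() <= image.min():
            return []
        thr = filters.threshold_otsu(image)
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_method='fixed' requires threshold_value")
        thr = threshold_value
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    if thr >= image.max():
        if threshold_method == "fixed":
            warnings.warn(f"threshold {thr} is above the image maximum; no detections", stacklevel=2)
        return []

    mask = image > thr
    if valid is not None:
        mask &= valid
    labeled = measure.label(mask, connectivity=2)
    detections = []
    for region in measure.regionprops(labeled, intensity_image=image):
        if weighted_centroid:
            r, c = region.centroid_weighted
        else:
            r, c = region.centroid
        detections.append(
            Detection(
                frame=frame,
                plane=plane,
                centroid_um=((c + 0.5) * pixel_size_xy, (r + 0.5) * pixel_size_xy),
                area_um2=region.area * pixel_size_xy**2,
                pixels=region.coords.copy(),
                label=region.label,
                total_intensity=float(region.image_intensity.sum()),
            )
        )
    return detections


def filter_by_size(
    detections: list[Detection], min_area_um2: float, max_area_um2: float
) -> tuple[list[Detection], dict[str, int]]:
    """Keep detections with ``min_area <= area <= max_area``.

    Returns the kept detections and counts of removals:
    ``{"removed_small": ..., "removed_large": ...}``.
    """
    if not min_area_um2 < max_area_um2:
        raise ValueError("min_area_um2 must be < max_area_um2")
    kept, n_small, n_large = [], 0, 0
    for det in detections:
        if det.area_um2 < min_area_um2:
            n_small += 1
        elif det.area_um2 > max_area_um2:
            n_large += 1
        else:
            kept.append(det)
    return kept, {"removed_small": n_small, "removed_large": n_large}


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def collapse_z(detections: list[Detection], match_radius_um: float) -> list[Detection]:
    """Collapse multi-plane appearances of one cell to its maximal-area plane.

    Detections of the same frame in *adjacent* planes whose centroids lie
    within ``match_radius_um`` are grouped (transitively); only the group
    member with maximal area survives.  Ties are broken deterministically:
    lower plane index first, then higher total intensity, then lower label.
    """
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)

    survivors: list[Detection] = []
    for frame in sorted(by_frame):
        dets = sorted(by_frame[frame], key=lambda d: (d.plane, d.label))
        uf = _UnionFind(len(dets))
        for i in range(len(dets)):
            for j in range(i + 1, len(dets)):
                if abs(dets[i].plane - dets[j].plane) == 1 and dets[i].distance_to(dets[j]) <= match_radius_um:
                    uf.union(i, j)
        groups: dict[int, list[Detection]] = {}
        for i, det in enumerate(dets):
            groups.setdefault(uf.find(i), []).append(det)
        for members in groups.values():
            best = min(members, key=lambda d: (-d.area_um2, d.plane, -d.total_intensity, d.label))
            survivors.append(best)
    return survivors


def detections_to_dataframe(detections: list[Detection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [d.frame for d in detections],
            "plane": [d.plane for d in detections],
            "x_um": [d.x for d in detections],
            "y_um": [d.y for d in detections],
            "area_um2": [d.area_um2 for d in detections],
            "label": [d.label for d in detections],
        }
    )
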