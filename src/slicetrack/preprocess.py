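"""Drift correction and cell-channel cleanup.

The processing order is fixed: drift correction first (estimated from the
ECM channel), then bleed-through subtraction and background removal, then
median smoothing.  All steps record their effective parameters so runs are
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters
from skimage.registration import phase_cross_correlation

from slicetrack.image_io import ImageStack

__all__ = [
    "DriftModel",
    "estimate_drift",
    "apply_drift",
    "correct_cell_channel",
    "estimate_bleed_coeff",
]


@dataclass
class DriftModel:
    """Per-frame translations (dx, dy) in px relative to frame 0.

    ``shifts[t]`` is the cumulative displacement of frame ``t``'s content
    with respect to frame 0; the transform for frame 0 is the identity.
    """

    shifts: np.ndarray  # (T, 2) (dx, dy) px
    residuals: np.ndarray  # (T,) per-frame estimation residual, px
    thetas: np.ndarray | None = None  # optional per-frame rotation, rad
    method_per_frame: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must have shape (T, 2)")
        if len(self.residuals) != len(self.shifts):
            raise ValueError("residuals length must match shifts")
        if not np.allclose(self.shifts[0], 0.0):
            raise ValueError("transform for frame 0 must be the identity")
        if np.any(self.residuals < 0):
            raise ValueError("residuals must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.shifts)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "dx": self.shifts[:, 0],
                "dy": self.shifts[:, 1],
                "theta": self.thetas if self.thetas is not None else np.zeros(self.n_frames),
                "residual": self.residuals,
            }
        )
        if self.method_per_frame:
            df["method"] = self.method_per_frame
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DriftModel":
        df = pd.read_csv(path)
        thetas = df["theta"].to_numpy() if "theta" in df else None
        return cls(
            shifts=df[["dx", "dy"]].to_numpy(),
            residuals=df["residual"].to_numpy(),
            thetas=thetas,
            method_per_frame=list(df["method"]) if "method" in df else [],
        )


def _pairwise_translation_features(
    ref: np.ndarray, mov: np.ndarray, min_matches: int
) -> tuple[np.ndarray, float] | None:
    """Estimate translation by ORB keypoint matching; None when too few matches.

    Returns the (dx, dy) displacement of ``mov``'s content relative to
    ``ref`` and a residual (median absolute deviation of the matched
    displacement vectors).
    """
    orb = feature.ORB(n_keypoints=200, fast_threshold=0.05)
    try:
        orb.detect_and_extract(ref.astype(float))
        kp_ref, desc_ref = orb.keypoints, orb.descriptors
        orb.detect_and_extract(mov.astype(float))
        kp_mov, desc_mov = orb.keypoints, orb.descriptors
    except RuntimeError:  # no keypoints found
        return None
    if len(kp_ref) < min_matches or len(kp_mov) < min_matches:
        return None
    matches = feature.match_descriptors(desc_ref, desc_mov, cross_check=True)
    if len(matches) < min_matches:
        return None
    disp = kp_mov[matches[:, 1]] - kp_ref[matches[:, 0]]  # (row, col) displacements
    med = np.median(disp, axis=0)
    spread = np.median(np.abs(disp - med), axis=0)
    # reject outlier matches, re-estimate
    keep = np.all(np.abs(disp - med) <= np.maximum(3 * spread, 2.0), axis=1)
    if keep.sum() < min_matches:
        return None
    med = np.median(disp[keep], axis=0)
    residual = float(np.median(np.linalg.norm(disp[keep] - med, axis=1)))
    return np.array([med[1], med[0]]), residual  # -> (dx, dy)


def _pairwise_translation_phase(
    ref: np.ndarray, mov: np.ndarray, upsample: int
) -> tuple[np.ndarray, float]:
    shift, error, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample)
    # returned shift registers mov onto ref: mov content is displaced by -shift
    return np.array([-shift[1], -shift[0]]), float(error)


def estimate_drift(
    ecm_frames: np.ndarray,
    method: str = "features",
    min_matches: int = 8,
    upsample: int = 20,
    max_drift: float | None = None,
) -> DriftModel:
    """Estimate per-frame sample drift from the ECM channel.

    Matching features are detected in subsequent frame pairs and their
    coordinate displacements give the pairwise translation, refined to
    sub-pixel precision by phase correlation; pure phase correlation is the
    fallback when too few features match.  Pairwise transforms are composed
    into frame-0-referenced cumulative shifts.

    Parameters
    ----------
    ecm_frames:
        ``(T, Y, X)`` array (e.g. a single plane, or a Z-projection, of the
        ECM channel).
    method:
        ``"features"`` (default, with phase-correlation fallback) or
        ``"phase"`` (phase correlation only).
    """
    ecm_frames = np.asarray(ecm_frames, dtype=float)
    if ecm_frames.ndim != 3 or ecm_frames.shape[0] < 2:
        raise ValueError("need a (T, Y, X) array with at least 2 frames")
    if method not in ("features", "phase"):
        raise ValueError(f"unknown drift estimation method {method!r}")

    T = ecm_frames.shape[0]
    shifts = np.zeros((T, 2))
    residuals = np.zeros(T)
    methods = ["identity"]
    for t in range(1, T):
        ref, mov = ecm_frames[t - 1], ecm_frames[t]
        if ref.std() == 0 and mov.std() == 0:
            if np.array_equal(ref, mov):
                pairwise, res, used = np.zeros(2), 0.0, "identity"
            else:
                raise ValueError(f"frames {t - 1}->{t} are featureless; cannot estimate drift")
        else:
            pairwise = None
            used = "phase"
            if method == "features":
                est = _pairwise_translation_features(ref, mov, min_matches)
                if est is not None:
                    coarse, res = est
                    # sub-pixel refinement on the feature-aligned pair
                    aligned = ndi.shift(mov, (-coarse[1], -coarse[0]), order=1, mode="reflect")
                    fine, _ = _pairwise_translation_phase(ref, aligned, upsample)
                    pairwise = coarse + fine
                    used = "features"
            if pairwise is None:
                pairwise, res = _pairwise_translation_phase(ref, mov, upsample)
        shifts[t] = shifts[t - 1] + pairwise
        residuals[t] = res
        methods.append(used)
        if max_drift is not None and np.linalg.norm(pairwise) > max_drift:
            warnings.warn(
                f"estimated drift {np.linalg.norm(pairwise):.1f} px between frames "
                f"{t - 1} and {t} exceeds max_drift={max_drift}",
                stacklevel=2,
            )
    return DriftModel(shifts=shifts, residuals=residuals, method_per_frame=methods)


def apply_drift(stack: ImageStack, model: DriftModel) -> ImageStack:
    """Resample all channels into the frame-0 reference frame.

    Pixels whose content left the field of view are flagged in the returned
    stack's ``valid`` mask rather than silently zero-filled.
    """
    if model.n_frames != stack.n_frames:
        raise ValueError(
            f"drift model covers {model.n_frames} frames but stack has {stack.n_frames}"
        )
    data = np.empty_like(stack.data, dtype=np.float32)
    valid = np.ones((stack.n_frames, *stack.shape_yx), dtype=bool)
    ones = np.ones(stack.shape_yx, dtype=np.float32)
    for t in range(stack.n_frames):
        dx, dy = model.shifts[t]
        if dx == 0 and dy == 0:
            data[t] = stack.data[t]
            continue
        for z in range(stack.n_planes):
            for c in range(stack.data.shape[-1]):
                data[t, z, :, :, c] = ndi.shift(
                    stack.data[t, z, :, :, c].astype(np.float32),
                    (-dy, -dx),
                    order=1,
                    mode="constant",
                    cval=0.0,
                )
        coverage = ndi.shift(ones, (-dy, -dx), order=1, mode="constant", cval=0.0)
        valid[t] = coverage > 0.999
    if stack.valid is not None:
        valid &= stack.valid
    return ImageStack(
        data=data,
        pixel_size_xy=stack.pixel_size_xy,
        z_spacing=stack.z_spacing,
        frame_interval=stack.frame_interval,
        channel_roles=dict(stack.channel_roles),
        valid=valid,
    )


def estimate_bleed_coeff(cell: np.ndarray, ecm: np.ndarray) -> float:
    """Estimate the ECM->cell bleed-through coefficient from cell-free pixels.

    Uses the median ratio of (background-subtracted) cell intensity to ECM
    intensity over ECM-positive pixels; the median is robust to the minority
    of pixels actually occupied by cells.
    """
    cell = np.asarray(cell, dtype=float).ravel()
    ecm = np.asarray(ecm, dtype=float).ravel()
    if ecm.max() <= ecm.min():
        return 0.0
    thr = filters.threshold_otsu(ecm)
    sel = ecm > thr
    if not np.any(sel):
        return 0.0
    background = np.median(cell[~sel]) if np.any(~sel) else 0.0
    ratio = (cell[sel] - background) / ecm[sel]
    return float(max(np.median(ratio), 0.0))


def _background_floor(image: np.ndarray) -> float:
    """Robust background level: median of the lowest-intensity quartile."""
    vals = image.ravel()
    q25 = np.quantile(vals, 0.25)
    low = vals[vals <= q25]
    return float(np.median(low)) if low.size else 0.0


def correct_cell_channel(
    cell: np.ndarray,
    ecm: np.ndarray,
    bleed_coeff: float | None = None,
    median_radius: int = 1,
) -> np.ndarray:
    """Remove ECM bleed-through and background, then median-smooth.

    ``corrected = median_filter(max(cell - bleed_coeff*ecm - background, 0))``
    with the background estimated per frame as the median of the
    lowest-intensity quartile.  Arrays may carry leading (T, Z, ...) axes;
    filtering is applied per 2D (Y, X) image.

    When ``bleed_coeff`` is None it is estimated from cell-free pixels
    (see :func:`estimate_bleed_coeff`).
    """
    cell = np.asarray(cell, dtype=float)
    ecm = np.asarray(ecm, dtype=float)
    if cell.shape != ecm.shape:
        raise ValueError("cell and ECM images must be co-registered (same shape)")
    if bleed_coeff is None:
        bleed_coeff = estimate_bleed_coeff(cell, ecm)
    if bleed_coeff < 0:
        raise ValueError("bleed_coeff must be >= 0")

    flat_cell = cell.reshape(-1, *cell.shape[-2:])
    flat_ecm = ecm.reshape(-1, *ecm.shape[-2:])
    out = np.empty_like(flat_cell)
    size = 2 * median_radius + 1
    for i in range(flat_cell.shape[0]):
        sub = flat_cell[i] - bleed_coeff * flat_ecm[i]
        sub -= _background_floor(sub)
        np.clip(sub, 0.0, None, out=sub)
        out[i] = ndi.median_filter(sub, size=size) if median_radius > 0 else sub
    result = out.reshape(cell.shape)
    if result.max() == 0 and cell.max() > 0:
        warnings.warn("bleed-through correction produced an all-zero image", stacklevel=2)
    return result
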