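"""Calibrated image-stack and region-mask I/O.

Coordinate convention used throughout the package: pixel indices are
0-based and the physical position of a pixel *center* is
``(index + 0.5) * pixel_size``.  Plane ``k`` of a Z-stack sits at
``z = k * z_spacing`` (the bottom plane defines ``z = 0``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import tifffile
from skimage import filters, morphology

__all__ = [
    "ImageStack",
    "VolumeStack",
    "RegionMaskSet",
    "save_stack",
    "load_stack",
    "derive_region_masks",
    "save_region_masks",
    "load_region_masks",
]

_ROLES = ("cell", "ecm", "tumor")


@dataclass
class ImageStack:
    """A T x Z x Y x X x C intensity array with physical calibration.

    Parameters
    ----------
    data:
        5-dimensional intensity array ordered ``(T, Z, Y, X, C)``.
    pixel_size_xy:
        Lateral pixel size in micrometers per pixel.
    z_spacing:
        Distance between adjacent optical planes in micrometers.
    frame_interval:
        Time between frames in seconds.
    channel_roles:
        Mapping from role (``"cell"``, ``"ecm"``, ``"tumor"``) to channel
        index.  Must be injective.
    valid:
        Optional ``(T, Y, X)`` boolean mask of in-field pixels; pixels that
        left the field of view during drift correction are flagged False.
    """

    data: np.ndarray
    pixel_size_xy: float
    z_spacing: float
    frame_interval: float
    channel_roles: dict[str, int] = field(default_factory=dict)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"expected 5D (T,Z,Y,X,C) data, got {self.data.ndim}D")
        for name in ("pixel_size_xy", "z_spacing", "frame_interval"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        n_channels = self.data.shape[-1]
        indices = list(self.channel_roles.values())
        if len(set(indices)) != len(indices):
            raise ValueError("channel_roles must be injective")
        for role, idx in self.channel_roles.items():
            if role not in _ROLES:
                raise ValueError(f"unknown channel role {role!r}; expected one of {_ROLES}")
            if not 0 <= idx < n_channels:
                raise ValueError(
                    f"role {role!r} maps to channel {idx}, but stack has only {n_channels} channels"
                )
        if self.valid is not None and self.valid.shape != (
            self.data.shape[0],
            self.data.shape[2],
            self.data.shape[3],
        ):
            raise ValueError("valid mask must have shape (T, Y, X)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(T, Z, Y, X)`` sub-array for a channel role."""
        if role not in self.channel_roles:
            raise KeyError(f"stack has no channel with role {role!r}")
        return self.data[..., self.channel_roles[role]]


@dataclass
class VolumeStack:
    """A single-timepoint, single-channel 3D stack (Z, Y, X) with calibration."""

    data: np.ndarray
    pixel_size_xy: float
    z_spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D (Z,Y,X) data, got {self.data.ndim}D")
        if not self.pixel_size_xy > 0 or not self.z_spacing > 0:
            raise ValueError("calibration values must be > 0")


class RegionMaskSet:
    """Per-plane binary ECM and tumor masks.

    The tumor mask is by construction the logical complement of the ECM
    mask in every plane, mirroring the operational definition that
    fibronectin-negative area is tumor tissue.
    """

    def __init__(self, ecm: np.ndarray, source: str = "derived") -> None:
        ecm = np.asarray(ecm)
        if ecm.ndim != 3:
            raise ValueError(f"expected (Z, Y, X) mask array, got {ecm.ndim}D")
        if ecm.dtype != bool:
            values = np.unique(ecm)
            if not np.all(np.isin(values, (0, 1, 255))):
                raise ValueError(f"masks must be binary; found values {values[:10]}")
            ecm = ecm > 0
        if source not in ("manual", "derived"):
            raise ValueError("source must be 'manual' or 'derived'")
        self.ecm = ecm
        self.source = source

    @property
    def tumor(self) -> np.ndarray:
        return ~self.ecm

    @property
    def n_planes(self) -> int:
        return self.ecm.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.ecm.shape[1], self.ecm.shape[2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionMaskSet):
            return NotImplemented
        return bool(np.array_equal(self.ecm, other.ecm)) and self.source == other.source

    def region_at(self, plane: int, row: int, col: int) -> str:
        """Region label ('tumor' or 'ecm') at a pixel of a given plane."""
        return "ecm" if self.ecm[plane, row, col] else "tumor"


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

def save_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF (stored axis order TZCYX)."""
    path = Path(path)
    data = np.moveaxis(stack.data, -1, 2)  # TZYXC -> TZCYX
    names = [""] * stack.data.shape[-1]
    for role, idx in stack.channel_roles.items():
        names[idx] = role
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TZCYX",
            "PhysicalSizeX": stack.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_spacing,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": stack.frame_interval,
            "TimeIncrementUnit": "s",
            "Channel": {"Name": names},
        },
    )


def _parse_ome(xml: str) -> tuple[dict[str, float], list[str]]:
    root = ElementTree.fromstring(xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    cal: dict[str, float] = {}
    if pixels is not None:
        for attr, key in (
            ("PhysicalSizeX", "pixel_size_xy"),
            ("PhysicalSizeZ", "z_spacing"),
            ("TimeIncrement", "frame_interval"),
        ):
            if pixels.get(attr) is not None:
                cal[key] = float(pixels.get(attr))
    names = [c.get("Name") or "" for c in root.findall(".//ome:Channel", ns)]
    return cal, names


def load_stack(
    path: str | Path,
    calibration: dict[str, float] | None = None,
    channel_roles: dict[str, int] | None = None,
    axes: str | None = None,
) -> ImageStack:
    """Load a multi-page TIFF / OME-TIFF into a calibrated :class:`ImageStack`.

    Calibration (``pixel_size_xy``, ``z_spacing``, ``frame_interval``) is read
    from OME metadata when present; missing values must be supplied via
    ``calibration`` and are never silently defaulted.  ``axes`` overrides the
    axis order recorded in the file (a string over ``T``, ``Z``, ``C``,
    ``Y``, ``X``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = axes or series.axes
        meta_cal: dict[str, float] = {}
        names: list[str] = []
        if tif.ome_metadata:
            try:
                meta_cal, names = _parse_ome(tif.ome_metadata)
            except ElementTree.ParseError:
                pass

    file_axes = file_axes.upper().replace("S", "C").replace("Q", "Z")
    if len(file_axes) != data.ndim or set(file_axes) - set("TZCYX"):
        raise ValueError(
            f"cannot resolve axis order {file_axes!r} for {data.ndim}D data; "
            "pass axes= explicitly (string over T, Z, C, Y, X)"
        )
    if len(set(file_axes)) != len(file_axes):
        raise ValueError(f"ambiguous axis order {file_axes!r}: repeated axes")
    # expand missing axes, then order as TZYXC
    for ax in "TZCYX":
        if ax not in file_axes:
            data = data[np.newaxis]
            file_axes = ax + file_axes
    data = np.transpose(data, [file_axes.index(ax) for ax in "TZYXC"])

    cal = dict(meta_cal)
    if calibration:
        cal.update(calibration)
    missing = {"pixel_size_xy", "z_spacing", "frame_interval"} - set(cal)
    if missing:
        raise ValueError(
            f"calibration value(s) {sorted(missing)} absent from metadata; "
            "supply them explicitly via calibration="
        )

    if channel_roles is None:
        channel_roles = {n: i for i, n in enumerate(names) if n in _ROLES}
    for role, idx in channel_roles.items():
        if idx >= data.shape[-1]:
            raise ValueError(
                f"role {role!r} requests channel {idx}, but file has {data.shape[-1]} channels"
            )
    return ImageStack(
        data=data,
        pixel_size_xy=cal["pixel_size_xy"],
        z_spacing=cal["z_spacing"],
        frame_interval=cal["frame_interval"],
        channel_roles=channel_roles,
    )


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------

def derive_region_masks(
    stack: ImageStack,
    method: str = "otsu",
    threshold_value: float | None = None,
    min_area_um2: float = 25.0,
    closing_radius_um: float = 1.0,
) -> RegionMaskSet:
    """Derive ECM/tumor masks from the fibronectin (ECM) channel.

    Per plane, the temporally median-projected ECM channel is thresholded
    (Otsu by default), morphologically closed, and cleaned of objects
    smaller than ``min_area_um2``; tumor is the complement.
    """
    ecm = stack.channel("ecm").astype(float)
    if stack.valid is not None:
        ecm = ecm.copy()
        ecm[np.broadcast_to(~stack.valid[:, None], ecm.shape)] = np.nan
    if np.nanmax(ecm) == 0:
        raise ValueError("ECM channel is all-zero: no region structure to derive masks from")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixel columns
        proj = np.nanmedian(ecm, axis=0)  # (Z, Y, X)
    proj = np.nan_to_num(proj, nan=0.0)

    px = stack.pixel_size_xy
    min_px = max(1, int(round(min_area_um2 / px**2)))
    radius_px = max(1, int(round(closing_radius_um / px)))
    footprint = morphology.disk(radius_px)

    masks = np.empty(proj.shape, dtype=bool)
    for z in range(proj.shape[0]):
        plane = proj[z]
        if method == "otsu":
            thr = filters.threshold_otsu(plane) if plane.max() > plane.min() else np.inf
        elif method == "fixed":
            if threshold_value is None:
                raise ValueError("method='fixed' requires threshold_value")
            thr = threshold_value
        else:
            raise ValueError(f"unknown thresholding method {method!r}")
        mask = plane > thr
        mask = morphology.closing(mask, footprint)
        # remove objects/holes strictly smaller than min_px
        mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
        mask = morphology.remove_small_holes(mask, max_size=min_px - 1)
        masks[z] = mask
    return RegionMaskSet(masks, source="derived")


def save_region_masks(maskset: RegionMaskSet, directory: str | Path, prefix: str = "ecm") -> list[Path]:
    """Write per-plane ECM masks as 8-bit TIFFs (0/255) plus a provenance sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for z in range(maskset.n_planes):
        p = directory / f"{prefix}_z{z:02d}.tif"
        tifffile.imwrite(p, (maskset.ecm[z] * 255).astype(np.uint8))
        paths.append(p)
    sidecar = directory / f"{prefix}_masks.json"
    sidecar.write_text(
        json.dumps({"source": maskset.source, "n_planes": maskset.n_planes, "files": [p.name for p in paths]})
    )
    return paths


def load_region_masks(
    paths: list[str | Path],
    expected_shape: tuple[int, int] | None = None,
) -> RegionMaskSet:
    """Load per-plane binary ECM masks (one file per plane, bottom plane first)."""
    planes = []
    for z, p in enumerate(paths):
        img = tifffile.imread(p)
        if img.ndim != 2:
            raise ValueError(f"mask for plane {z} ({p}) is not a 2D image")
        if expected_shape is not None and img.shape != tuple(expected_shape):
            raise ValueError(
                f"mask for plane {z} ({p}) has shape {img.shape}, expected {tuple(expected_shape)}"
            )
        values = np.unique(img)
        if not np.all(np.isin(values, (0, 1, 255))):
            raise ValueError(f"mask for plane {z} ({p}) is not binary (values {values[:10]})")
        planes.append(img > 0)
    shapes = {m.shape for m in planes}
    if len(shapes) > 1:
        raise ValueError(f"mask planes disagree in shape: {sorted(shapes)}")
    return RegionMaskSet(np.stack(planes), source="manual")
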