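"""Synthetic two-compartment slice movies and Matrigel Z-stacks with ground truth.

The slice generator emulates a 3-channel (cell tracker / ECM marker / tumor
marker) multi-plane time-lapse acquisition: cells move as persistent random
walks whose step length depends on the compartment they currently occupy,
the whole scene drifts, the ECM channel bleeds into the cell channel, and
Poisson-Gaussian noise is added last.  Ground-truth trajectories are emitted
in specimen (drift-free) coordinates so downstream recovery is measurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from slicetrack.image_io import ImageStack, RegionMaskSet, VolumeStack

__all__ = [
    "SceneConfig",
    "CellTrack",
    "GroundTruthScene",
    "generate_slice_scene",
    "generate_matrigel_stack",
]


@dataclass
class SceneConfig:
    """Parameters of a synthetic slice-migration scene.

    Defaults mirror the reference acquisition geometry: 9 optical planes
    spanning 63 um of depth, one frame every 30 s.  Speeds are in um/min;
    ``turning_persistence`` in [0, 1] scales directional memory (1 = straight
    lines, 0 = fully random heading each step).
    """

    n_frames: int = 20
    n_planes: int = 9
    height: int = 256
    width: int = 256
    pixel_size_xy: float = 1.0
    z_spacing: float = 63.0 / 8.0
    frame_interval: float = 30.0
    n_cells: int = 20
    cell_radius: float = 5.0
    speed_tumor: float = 4.0
    speed_ecm: float = 2.0
    turning_persistence: float = 0.7
    n_islets: int = 3
    islet_radius_range: tuple[float, float] = (30.0, 60.0)
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    bleed_coeff: float = 0.2
    noise_sigma: float = 3.0
    poisson_gain: float = 1.0
    rng_seed: int = 0
    # rendering intensities (arbitrary units)
    cell_intensity: float = 180.0
    ecm_intensity: float = 150.0
    tumor_intensity: float = 120.0
    # optional behaviors
    min_separation: float | None = None
    placement_margin: float | None = None
    adjacent_plane_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_frames", "n_planes", "height", "width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("speed_tumor", "speed_ecm", "bleed_coeff", "noise_sigma", "poisson_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.turning_persistence <= 1.0:
            raise ValueError("turning_persistence must lie in [0, 1]")
        if self.cell_radius / self.pixel_size_xy < 1.0:
            raise ValueError(
                f"cell_radius of {self.cell_radius} um is below 1 px at "
                f"{self.pixel_size_xy} um/px; cells would be unrenderable"
            )

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical field extent (width_um, height_um)."""
        return self.width * self.pixel_size_xy, self.height * self.pixel_size_xy


@dataclass
class CellTrack:
    """Ground-truth trajectory of one simulated cell."""

    cell_id: int
    positions: np.ndarray  # (n_frames, 2) (x, y) in um, specimen coordinates
    plane: int
    regions: list[str]  # per-frame 'tumor' / 'ecm'

    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)


@dataclass
class GroundTruthScene:
    """Everything the generator knows: tracks, applied drift, region masks."""

    tracks: list[CellTrack]
    applied_drift: np.ndarray  # (n_frames, 2) cumulative (dx, dy) in px
    region_masks: RegionMaskSet
    config: SceneConfig | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "applied_drift": np.asarray(self.applied_drift).tolist(),
            "tracks": [
                {
                    "cell_id": t.cell_id,
                    "plane": t.plane,
                    "positions": np.asarray(t.positions).tolist(),
                    "regions": t.regions,
                }
                for t in self.tracks
            ],
        }
        if self.config is not None:
            payload["config"] = asdict(self.config)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path, region_masks: RegionMaskSet | None = None) -> "GroundTruthScene":
        payload = json.loads(Path(path).read_text())
        tracks = [
            CellTrack(
                cell_id=t["cell_id"],
                positions=np.asarray(t["positions"], dtype=float),
                plane=t["plane"],
                regions=list(t["regions"]),
            )
            for t in payload["tracks"]
        ]
        cfg = payload.get("config")
        if cfg is not None:
            cfg["islet_radius_range"] = tuple(cfg["islet_radius_range"])
            cfg["drift_per_frame"] = tuple(cfg["drift_per_frame"])
            cfg = SceneConfig(**cfg)
        masks = region_masks if region_masks is not None else RegionMaskSet(np.zeros((1, 1, 1), bool))
        return cls(
            tracks=tracks,
            applied_drift=np.asarray(payload["applied_drift"], dtype=float),
            region_masks=masks,
            config=cfg,
        )


# ---------------------------------------------------------------------------
# region geometry
# ---------------------------------------------------------------------------

def _make_region_masks(config: SceneConfig, rng: np.random.Generator) -> RegionMaskSet:
    """Tumor islets as random disks (constant across Z); ECM is the complement."""
    h, w = config.height, config.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy = (yy + 0.5) * config.pixel_size_xy
    cx = (xx + 0.5) * config.pixel_size_xy
    tumor = np.zeros((h, w), dtype=bool)
    lo, hi = config.islet_radius_range
    field_w, field_h = config.field_um
    for _ in range(config.n_islets):
        r = rng.uniform(lo, hi)
        x0 = rng.uniform(r, max(field_w - r, r))
        y0 = rng.uniform(r, max(field_h - r, r))
        tumor |= (cx - x0) ** 2 + (cy - y0) ** 2 <= r**2
    coverage = tumor.mean()
    if coverage in (0.0, 1.0) and config.speed_tumor != config.speed_ecm:
        warnings.warn(
            f"tumor islets cover {coverage:.0%} of the field; region-dependent "
            "speed recovery is untestable on this scene",
            stacklevel=3,
        )
    ecm = ~tumor
    return RegionMaskSet(np.repeat(ecm[np.newaxis], config.n_planes, axis=0), source="manual")


def _region_of(masks: RegionMaskSet, plane: int, x_um: float, y_um: float, pixel_size: float) -> str:
    h, w = masks.shape_yx
    col = min(max(int(x_um / pixel_size), 0), w - 1)
    row = min(max(int(y_um / pixel_size), 0), h - 1)
    return masks.region_at(plane, row, col)


def _place_cells(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    field_w, field_h = config.field_um
    margin = config.placement_margin if config.placement_margin is not None else 2 * config.cell_radius
    margin = min(margin, 0.4 * min(field_w, field_h))
    positions = np.empty((config.n_cells, 2))
    for i in range(config.n_cells):
        for _ in range(10_000):
            p = rng.uniform([margin, margin], [field_w - margin, field_h - margin])
            if config.min_separation is None or i == 0:
                break
            if np.min(np.linalg.norm(positions[:i] - p, axis=1)) >= config.min_separation:
                break
        else:
            raise RuntimeError(
                f"could not place {config.n_cells} cells with min_separation="
                f"{config.min_separation} um in a {field_w:.0f}x{field_h:.0f} um field"
            )
        positions[i] = p
    return positions


def _simulate_walks(
    config: SceneConfig, masks: RegionMaskSet, rng: np.random.Generator
) -> list[CellTrack]:
    """Persistent random walks with region-dependent fixed step length."""
    dt_min = config.frame_interval / 60.0
    step_len = {"tumor": config.speed_tumor * dt_min, "ecm": config.speed_ecm * dt_min}
    field_w, field_h = config.field_um
    turn_sigma = (1.0 - config.turning_persistence) * np.pi

    start = _place_cells(config, rng)
    planes = rng.integers(0, config.n_planes, size=config.n_cells)
    headings = rng.uniform(0, 2 * np.pi, size=config.n_cells)

    tracks = []
    for i in range(config.n_cells):
        pos = start[i].copy()
        theta = headings[i]
        positions = np.empty((config.n_frames, 2))
        regions: list[str] = []
        for t in range(config.n_frames):
            positions[t] = pos
            regions.append(_region_of(masks, planes[i], pos[0], pos[1], config.pixel_size_xy))
            if t == config.n_frames - 1:
                break
            theta += rng.normal(0.0, turn_sigma)
            length = step_len[regions[-1]]
            # reflect the heading (not the position) off field borders so the
            # recorded step length stays exactly speed * dt everywhere
            for _ in range(8):
                cand = pos + length * np.array([np.cos(theta), np.sin(theta)])
                if 0.0 <= cand[0] <= field_w and 0.0 <= cand[1] <= field_h:
                    break
                if cand[0] < 0.0 or cand[0] > field_w:
                    theta = np.pi - theta
                if cand[1] < 0.0 or cand[1] > field_h:
                    theta = -theta
            pos = np.clip(cand, [0.0, 0.0], [field_w, field_h])
        tracks.append(CellTrack(cell_id=i, positions=positions, plane=int(planes[i]), regions=regions))
    return tracks


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_blob(
    image: np.ndarray, x_um: float, y_um: float, sigma_px: float, amplitude: float, pixel_size: float
) -> None:
    """Add a 2D Gaussian blob (in place), evaluated on a local window only."""
    h, w = image.shape
    cx = x_um / pixel_size - 0.5  # pixel-center convention
    cy = y_um / pixel_size - 0.5
    half = int(np.ceil(4 * sigma_px))
    c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
    r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
    c0, c1 = max(c0, 0), min(c1, w)
    r0, r1 = max(r0, 0), min(r1, h)
    if c0 >= c1 or r0 >= r1:
        return
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    gx = np.exp(-((cols - cx) ** 2) / (2 * sigma_px**2))
    gy = np.exp(-((rows - cy) ** 2) / (2 * sigma_px**2))
    image[r0:r1, c0:c1] += amplitude * np.outer(gy, gx)


def generate_slice_scene(
    config: SceneConfig,
) -> tuple[ImageStack, RegionMaskSet, GroundTruthScene]:
    """Generate a 3-channel slice movie plus masks and ground truth.

    Channel order is fixed: 0 = cell tracker, 1 = ECM marker, 2 = tumor
    marker.  Ground truth is returned in specimen (drift-free) coordinates;
    the rendered images carry the cumulative drift.
    """
    rng = np.random.default_rng(config.rng_seed)
    masks = _make_region_masks(config, rng)
    tracks = _simulate_walks(config, masks, rng)

    drift_step = np.asarray(config.drift_per_frame, dtype=float)
    cumulative_drift = np.outer(np.arange(config.n_frames), drift_step)  # (T, 2) px

    h, w = config.height, config.width
    sigma_px = config.cell_radius / config.pixel_size_xy / 2.0
    data = np.zeros((config.n_frames, config.n_planes, h, w, 3), dtype=np.float32)

    ecm_img = masks.ecm.astype(np.float32) * config.ecm_intensity  # (Z, Y, X)
    tumor_img = masks.tumor.astype(np.float32) * config.tumor_intensity

    for t in range(config.n_frames):
        frame = np.zeros((config.n_planes, h, w, 3), dtype=np.float32)
        frame[..., 1] = ecm_img
        frame[..., 2] = tumor_img
        for track in tracks:
            x, y = track.positions[t]
            _render_blob(
                frame[track.plane, :, :, 0], x, y, sigma_px, config.cell_intensity, config.pixel_size_xy
            )
            if config.adjacent_plane_fraction > 0:
                for dz in (-1, 1):
                    p = track.plane + dz
                    if 0 <= p < config.n_planes:
                        _render_blob(
                            frame[p, :, :, 0],
                            x,
                            y,
                            sigma_px * np.sqrt(config.adjacent_plane_fraction),
                            config.cell_intensity * config.adjacent_plane_fraction,
                            config.pixel_size_xy,
                        )
        frame[..., 0] += config.bleed_coeff * frame[..., 1]
        dx, dy = cumulative_drift[t]
        if dx != 0 or dy != 0:
            for z in range(config.n_planes):
                for c in range(3):
                    frame[z, :, :, c] = ndi.shift(
                        frame[z, :, :, c], (dy, dx), order=1, mode="reflect"
                    )
        data[t] = frame

    if config.poisson_gain > 0:
        data = rng.poisson(data / config.poisson_gain).astype(np.float32) * config.poisson_gain
    if config.noise_sigma > 0:
        data = data + rng.normal(0.0, config.noise_sigma, size=data.shape).astype(np.float32)

    stack = ImageStack(
        data=data,
        pixel_size_xy=config.pixel_size_xy,
        z_spacing=config.z_spacing,
        frame_interval=config.frame_interval,
        channel_roles={"cell": 0, "ecm": 1, "tumor": 2},
    )
    truth = GroundTruthScene(
        tracks=tracks, applied_drift=cumulative_drift, region_masks=masks, config=config
    )
    return stack, masks, truth


# ---------------------------------------------------------------------------
# Matrigel stacks
# ---------------------------------------------------------------------------

def generate_matrigel_stack(
    n_cells: int,
    z_extent: float = 160.0,
    z_step: float = 2.0,
    xy_extent: float = 200.0,
    pixel_size_xy: float = 1.0,
    placement: str | np.ndarray = "uniform",
    nucleus_radius: float = 4.0,
    noise_sigma: float = 0.0,
    poisson_gain: float = 0.0,
    min_separation: float | None = None,
    intensity: float = 200.0,
    seed: int = 0,
) -> tuple[VolumeStack, np.ndarray]:
    """Generate a single-timepoint 3D nuclei stack plus true centroids.

    ``placement`` is either ``"uniform"`` (xyz uniform in the volume), a 1D
    array of z positions (xy drawn uniformly), or an ``(n, 3)`` array of
    explicit ``(x, y, z)`` positions in um.  z is measured upward from the
    bottom plane (plane ``k`` sits at ``z = k * z_step``).
    """
    if z_step <= 0:
        raise ValueError("z_step must be > 0")
    rng = np.random.default_rng(seed)
    n_planes = int(np.floor(z_extent / z_step)) + 1
    npx = int(round(xy_extent / pixel_size_xy))
    margin = 2 * nucleus_radius

    if isinstance(placement, str):
        if placement != "uniform":
            raise ValueError(f"unknown placement {placement!r}")
        centroids = np.empty((n_cells, 3))
        for i in range(n_cells):
            for _ in range(10_000):
                p = rng.uniform(
                    [margin, margin, 0.0],
                    [xy_extent - margin, xy_extent - margin, z_extent],
                )
                if min_separation is None or i == 0:
                    break
                if np.min(np.linalg.norm(centroids[:i] - p, axis=1)) >= min_separation:
                    break
            else:
                raise RuntimeError(
                    f"cannot place {n_cells} nuclei with min_separation={min_separation} um "
                    f"in a {xy_extent}x{xy_extent}x{z_extent} um volume"
                )
            centroids[i] = p
    else:
        placement = np.asarray(placement, dtype=float)
        if placement.ndim == 1:
            if len(placement) != n_cells:
                raise ValueError("z placement array length must equal n_cells")
            xy = _scatter_xy(n_cells, xy_extent, margin, min_separation, rng)
            centroids = np.column_stack([xy, placement])
        elif placement.shape == (n_cells, 3):
            centroids = placement.copy()
        else:
            raise ValueError("placement must be 'uniform', (n,) z array or (n, 3) xyz array")

    data = np.zeros((n_planes, npx, npx), dtype=np.float32)
    sig_xy = nucleus_radius / pixel_size_xy / 2.0
    sig_z = nucleus_radius / z_step / 2.0
    for x, y, z in centroids:
        _render_blob_3d(data, x, y, z, sig_xy, sig_z, intensity, pixel_size_xy, z_step)

    if poisson_gain > 0:
        data = rng.poisson(data / poisson_gain).astype(np.float32) * poisson_gain
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape).astype(np.float32)

    return VolumeStack(data=data, pixel_size_xy=pixel_size_xy, z_spacing=z_step), centroids


def _scatter_xy(
    n: int, xy_extent: float, margin: float, min_separation: float | None, rng: np.random.Generator
) -> np.ndarray:
    xy = np.empty((n, 2))
    for i in range(n):
        for _ in range(10_000):
            p = rng.uniform([margin, margin], [xy_extent - margin, xy_extent - margin])
            if min_separation is None or i == 0:
                break
            if np.min(np.linalg.norm(xy[:i] - p, axis=1)) >= min_separation:
                break
        else:
            raise RuntimeError("xy placement with requested min_separation is infeasible")
        xy[i] = p
    return xy


def _render_blob_3d(
    volume: np.ndarray,
    x_um: float,
    y_um: float,
    z_um: float,
    sigma_xy_px: float,
    sigma_z_planes: float,
    amplitude: float,
    pixel_size: float,
    z_step: float,
) -> None:
    nz, h, w = volume.shape
    cx = x_um / pixel_size - 0.5
    cy = y_um / pixel_size - 0.5
    cz = z_um / z_step  # plane k is at z = k * z_step
    half_xy = int(np.ceil(4 * sigma_xy_px))
    half_z = int(np.ceil(4 * sigma_z_planes))
    c0, c1 = max(int(np.floor(cx)) - half_xy, 0), min(int(np.floor(cx)) + half_xy + 1, w)
    r0, r1 = max(int(np.floor(cy)) - half_xy, 0), min(int(np.floor(cy)) + half_xy + 1, h)
    z0, z1 = max(int(np.floor(cz)) - half_z, 0), min(int(np.floor(cz)) + half_z + 1, nz)
    if c0 >= c1 or r0 >= r1 or z0 >= z1:
        return
    gx = np.exp(-((np.arange(c0, c1) - cx) ** 2) / (2 * sigma_xy_px**2))
    gy = np.exp(-((np.arange(r0, r1) - cy) ** 2) / (2 * sigma_xy_px**2))
    gz = np.exp(-((np.arange(z0, z1) - cz) ** 2) / (2 * sigma_z_planes**2))
    volume[z0:z1, r0:r1, c0:c1] += amplitude * gz[:, None, None] * np.outer(gy, gx)[None]
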