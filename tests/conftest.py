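import numpy as np
import pytest

from slicetrack.detect import Detection
from slicetrack.synth import SceneConfig, generate_slice_scene


@pytest.fixture(scope="session")
def noisy_scene():
    """Small default-noise scene shared by read-only tests."""
    config = SceneConfig(
        n_frames=10,
        n_planes=2,
        n_cells=10,
        height=200,
        width=200,
        rng_seed=42,
        min_separation=25.0,
    )
    return config, *generate_slice_scene(config)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, bleed-free scene with well-separated cells."""
    config = SceneConfig(
        n_frames=8,
        n_planes=1,
        n_cells=10,
        height=220,
        width=220,
        rng_seed=7,
        noise_sigma=0.0,
        poisson_gain=0.0,
        bleed_coeff=0.0,
        min_separation=30.0,
    )
    return config, *generate_slice_scene(config)


@pytest.fixture
def make_detection():
    """Factory for synthetic detections with sensible defaults."""

    def _make(frame=0, x=0.0, y=0.0, plane=0, area=50.0, pixels=None, label=0, intensity=100.0):
        if pixels is None:
            pixels = np.array([[int(y), int(x)]])
        return Detection(
            frame=frame,
            plane=plane,
            centroid_um=(float(x), float(y)),
            area_um2=float(area),
            pixels=np.asarray(pixels),
            label=label,
            total_intensity=intensity,
        )

    return _make
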