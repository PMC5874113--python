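import numpy as np
import pytest
from scipy import ndimage

from resptrack import (
    ImageGrid,
    MarkerSpec,
    MotionModelParams,
    PhantomScene,
    reference_params,
    reference_scene,
    render_sequence,
)


@pytest.fixture(scope="session")
def textured_frame() -> ImageGrid:
    """Smooth random texture with gradients everywhere: good LK terrain."""
    rng = np.random.default_rng(42)
    img = ndimage.gaussian_filter(rng.random((128, 128)), sigma=2.0)
    img = (img - img.min()) / np.ptp(img)
    return ImageGrid(img)


@pytest.fixture(scope="session")
def small_phantom():
    """A tiny noiseless phantom sequence with its ground truth."""
    scene = reference_scene(
        amplitude_mm=10.0, pixel_scale_px_per_mm=4.0, noise_sd=0.0, marker_size_mm=8.0
    )
    frames, truth = render_sequence(
        scene, MotionModelParams(30.0, 10.0, 0.2), fps=30.0, duration_s=2.0, seed=7
    )
    return scene, frames, truth


@pytest.fixture(scope="session")
def disc_scene():
    """Three noiseless discs for detection tests."""
    markers = [
        MarkerSpec(centre_mm=(8.0, 8.0), size_mm=6.0, shape="disc"),
        MarkerSpec(centre_mm=(24.0, 9.5), size_mm=6.0, shape="disc"),
        MarkerSpec(centre_mm=(16.0, 22.0), size_mm=6.0, shape="disc"),
    ]
    scene = PhantomScene(
        markers=markers,
        pixel_scale_px_per_mm=4.0,
        image_size_px=(128, 128),
        noise_sd=0.0,
    )
    frames, truth = render_sequence(
        scene, MotionModelParams(30.0, 0.0, 0.0), fps=30.0, duration_s=0.1, seed=0
    )
    return scene, frames[0], truth
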