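import numpy as np
import pytest

from fibermesh import io as fio
from fibermesh import synth


@pytest.fixture(scope="session")
def cal():
    return fio.Calibration(um_per_px=0.05)


@pytest.fixture(scope="session")
def small_mesh():
    """20 disjoint fibers on 512 px: fast, used by most image-path tests."""
    spec = synth.MeshSpec(
        image_width_px=512,
        image_height_px=512,
        um_per_px=0.05,
        n_fibers=20,
        diameter_law=synth.DiameterLaw("lognormal", 0.48, 0.586),
        placement="segment",
        allow_overlap=False,
        fiber_length_px=(120, 220),
        seed=7,
    )
    return spec, *synth.generate_mesh(spec)


@pytest.fixture(scope="session")
def medium_mesh():
    """60 disjoint fibers on 1024 px under the study's diameter law."""
    spec = synth.MeshSpec(
        image_width_px=1024,
        image_height_px=1024,
        um_per_px=0.05,
        n_fibers=60,
        diameter_law=synth.DiameterLaw("lognormal", 0.48, 0.586),
        placement="segment",
        allow_overlap=False,
        fiber_length_px=(200, 300),
        seed=11,
    )
    return spec, *synth.generate_mesh(spec)


@pytest.fixture()
def horizontal_fiber():
    """One straight horizontal fiber spanning a 512-px-wide image, d = 10 px."""
    poly = np.array([[256.0, 0.0], [256.0, 511.0]])
    image, truth = synth.render_fibers(
        [poly],
        np.array([0.5]),  # 10 px at 0.05 um/px
        image_width_px=512,
        image_height_px=512,
        um_per_px=0.05,
        noise_sd=0.0,
    )
    return image, truth
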