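import numpy as np
import pytest

from collagenfft import phantom
from collagenfft.afm_io import AFMImage

#: default physiological D-band search band (nm)
BAND = (40.0, 110.0)

#: pixel size of the reference 5 µm / 512 px calibration
PIXEL_NM = 5000.0 / 512


@pytest.fixture(scope="session")
def render_preset():
    """Session-cached phantom renderer: render_preset(name) -> (AFMImage, truth)."""
    cache: dict[str, tuple] = {}

    def render(name: str):
        if name not in cache:
            cache[name] = phantom.render_phantom(phantom.preset(name))
        return cache[name]

    return render


@pytest.fixture
def make_noise_tile():
    """Seeded isotropic white-noise tile (structureless input)."""

    def make(seed: int, n: int = 128) -> AFMImage:
        rng = np.random.default_rng(seed)
        width = n * PIXEL_NM / 1000.0
        return AFMImage(pixels=rng.normal(0.0, 1.0, (n, n)), width_um=width, height_um=width)

    return make


def small_phantom_spec(angles, n_fibrils=30, px=256, seed=0, noise=0.05, d_period=64.0):
    """Reduced-size phantom at the reference pixel calibration."""
    return phantom.PhantomSpec(
        image_px=px,
        width_um=px * PIXEL_NM / 1000.0,
        groups=tuple(
            phantom.FibrilGroup(orientation_deg=float(a), n_fibrils=n_fibrils, d_period_nm=d_period)
            for a in angles
        ),
        noise_sd=noise,
        seed=seed,
    )


def axial_diff(a: float, b: float) -> float:
    """Smallest difference between two axial (180°-periodic) angles."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)
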