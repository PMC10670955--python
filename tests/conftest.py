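import numpy as np
import pytest

from uroquant import density, phantom


@pytest.fixture(scope="session")
def clean_straight():
    """Noiseless straight-band phantom with exact ground truth."""
    params = phantom.TissuePhantomParams(seed=11)
    return phantom.generate_tissue_phantom(params)


@pytest.fixture(scope="session")
def clean_arc():
    params = phantom.TissuePhantomParams(
        centerline_kind="arc", arc_radius_um=50.0,
        image_height_px=320, image_width_px=320, seed=12,
    )
    return phantom.generate_tissue_phantom(params)


@pytest.fixture()
def phantom_factory():
    """Factory for phantoms across centerline kinds and noise levels."""

    def make(kind: str = "straight", seed: int = 0, **overrides):
        kw = dict(centerline_kind=kind, seed=seed)
        if kind == "arc":
            kw.update(arc_radius_um=50.0, image_height_px=320, image_width_px=320)
        kw.update(overrides)
        return phantom.generate_tissue_phantom(phantom.TissuePhantomParams(**kw))

    return make


@pytest.fixture()
def rectangle_band():
    """200 x 20 px solid band at 0.5 um/px: centerline 100 um."""
    mask = np.zeros((60, 220), dtype=bool)
    mask[20:40, 10:210] = True
    return density.BandMask(mask=mask, pixel_size_um=0.5), 100.0


@pytest.fixture()
def half_circle_band():
    """Half annulus, centerline radius 50 um at 0.5 um/px: pi * 50 um."""
    rr, cc = np.mgrid[0:140, 0:260]
    radius = np.hypot(rr - 120.0, cc - 130.0)
    mask = (np.abs(radius - 100.0) <= 10.0) & (rr <= 120)
    return density.BandMask(mask=mask, pixel_size_um=0.5), float(np.pi * 50.0)
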