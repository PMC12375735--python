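import numpy as np
import pytest

from vesselmorph.synthetic import (
    NoiseModel,
    VesselNetworkSpec,
    VesselSegment,
    render_network,
)


@pytest.fixture(scope="session")
def clean_capsule():
    """A noise-free, blur-free horizontal capsule: radius 5 µm, length 100 µm."""
    seg = VesselSegment((50.0, 20.0), (50.0, 120.0), 5.0)
    spec = VesselNetworkSpec(
        (seg,),
        image_shape=(100, 150),
        psf_sigma=0.0,
        noise_model=NoiseModel("none"),
    )
    image, mask, truth = render_network(spec)
    return spec, image, mask, truth


def render_clean_capsule(radius: float, length: float = 100.0, pad: float = 20.0):
    """Render one noise-free capsule of the given radius at 1 µm/pixel."""
    y = radius + pad
    seg = VesselSegment((y, pad), (y, pad + length), radius)
    shape = (int(2 * y) + 1, int(length + 2 * pad) + 1)
    spec = VesselNetworkSpec(
        (seg,), image_shape=shape, psf_sigma=0.0, noise_model=NoiseModel("none")
    )
    return render_network(spec)
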