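import numpy as np
import pytest

from scarmorph import SectionSpec, generate_section_image


@pytest.fixture(scope="session")
def quiet_section():
    """Small noiseless section with nuclei/vessels/fibres, shared read-only."""
    spec = SectionSpec(width_um=400.0, height_um=300.0, pixel_size_um=1.0,
                       nuclei_density_per_mm2=600.0, ki67_fraction=0.15,
                       vessel_area_fraction=0.06, fibre_area_fraction=0.3,
                       seed=42)
    image, truth = generate_section_image(spec)
    return spec, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
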