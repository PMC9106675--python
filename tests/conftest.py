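import pytest

from ppidrugg.pocket_descriptors import PocketConfig
from ppidrugg.synthetic_data import CavitySpec, make_cavity_structure


@pytest.fixture(scope="session")
def default_cavity():
    """Standard carved-cavity fixture (radius 4 A, depth 6 A, apolar)."""
    return make_cavity_structure(CavitySpec())


@pytest.fixture(scope="session")
def polar_cavity():
    """Same geometry with half the lining atoms polar."""
    return make_cavity_structure(CavitySpec(polar_fraction=0.5))


@pytest.fixture(scope="session")
def flat_slab():
    """Flat, pocket-less interface (the ZipA-like regime)."""
    return make_cavity_structure(CavitySpec(depth=0.0))


@pytest.fixture(scope="session")
def mini_config():
    """Small descriptor config usable with the pure-Python oracle."""
    return PocketConfig(region_margin=3.0, ray_length=6.0)


@pytest.fixture(scope="session")
def mini_cavity():
    """Tiny cavity the brute-force oracle can handle in seconds."""
    return make_cavity_structure(
        CavitySpec(
            radius=3.0,
            depth=4.0,
            polar_fraction=0.5,
            slab_half_width=7.0,
            slab_thickness=8.0,
            seed=3,
        )
    )
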