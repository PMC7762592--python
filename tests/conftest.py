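import pytest

from capsidkit.allometry import printed_fit
from capsidkit.cage import build_cage_hk
from capsidkit.predictor import default_t_grid


@pytest.fixture(scope="session")
def genome_fit():
    """Published genome-length model G(T) = 10^0.37 * T^1.47 (kbp)."""
    return printed_fit("genome_kbp")


@pytest.fixture(scope="session")
def diameter_fit():
    """Published capsid-diameter model D(T) = 10^1.38 * T^0.52 (nm)."""
    return printed_fit("diameter_nm")


@pytest.fixture(scope="session")
def t_series():
    """Deduplicated generalized T grid with T < 40."""
    return default_t_grid()


#: the small-capsid model set (every lattice at t <= 4) plus a T=7 control
CAGE_SET = [
    ("hexagonal", 1, 0),
    ("hexagonal", 1, 1),
    ("hexagonal", 2, 0),
    ("hexagonal", 2, 1),
    ("trihexagonal", 1, 0),
    ("trihexagonal", 1, 1),
    ("snub_hexagonal", 1, 0),
    ("rhombitrihexagonal", 1, 0),
]


@pytest.fixture(scope="session")
def cage_meshes():
    """Session-cached cage meshes for the small-capsid set (sphericity 0)."""
    return {(lat, h, k): build_cage_hk(h, k, lat) for lat, h, k in CAGE_SET}
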