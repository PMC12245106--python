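import numpy as np
import pytest

from bhicc.dose_response import HillParams
from bhicc.packing import LatticeSpec
from bhicc.synth import build_void_lattice, simulate_volume

DOSES = (0.0, 10.0, 20.0, 50.0, 100.0, 200.0)

# printed fit parameters used as generator ground truths
HC_PARAMS = {"HepG2": HillParams(ic50=18.92, n=2.807), "LNCaP": HillParams(ic50=12.98, n=1.252)}
HT_PARAMS = {"HepG2": HillParams(ic50=25.69, n=1.310), "LNCaP": HillParams(ic50=20.45, n=0.9572)}


@pytest.fixture(scope="session")
def small_lattice():
    """Single-layer lattice of ~20 voids of 250 um in a small dish."""
    spec = LatticeSpec(void_diameter=250.0, container_diameter=1450.0)
    return build_void_lattice(spec, seed=11)


@pytest.fixture(scope="session")
def noiseless_volume(small_lattice):
    """Noiseless half-viability volume with ground truth."""
    hill = HillParams(ic50=20.0, n=2.0)
    return simulate_volume(
        small_lattice, diam_mean=179.2, diam_sd=9.76, dose=20.0, hill=hill,
        noise={"gauss_sd": 0.0, "poisson_gain": 0.0}, seed=7,
    )


@pytest.fixture(scope="session")
def noisy_volume(small_lattice):
    """Default-noise volume at 30 % dead fraction with ground truth."""
    hill = HillParams(ic50=20.0, n=1.0)
    # dose chosen so hill gives viability 0.70: (d/20)^1 = 3/7
    dose = 20.0 * 3.0 / 7.0
    return simulate_volume(
        small_lattice, diam_mean=179.2, diam_sd=9.76, dose=dose, hill=hill, seed=13,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
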