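import numpy as np
import pytest

from acidfba import (TOYEC1, build_acidfba, build_xi, make_toy_ecgem)
from acidfba.toys import CarbonSource


@pytest.fixture(scope="session")
def toyec1():
    """Classified ToyEC-1 ecGEM plus its protein records."""
    ec, proteins = make_toy_ecgem(TOYEC1)
    return ec, proteins


@pytest.fixture(scope="session")
def toyec1_acid(toyec1):
    """ToyEC-1 rebuilt as an acidFBA model (uptake-and-pool limited)."""
    ec, proteins = toyec1
    return build_acidfba(ec, build_xi(proteins))


@pytest.fixture(scope="session")
def enzyme_limited_acid():
    """ToyEC-1 variant whose only binding constraint is the protein pool."""
    spec = TOYEC1.with_(uptake=1.0e6)
    ec, proteins = make_toy_ecgem(spec)
    return build_acidfba(ec, build_xi(proteins)), spec


@pytest.fixture(scope="session")
def nutrient_toy():
    """Toy with C/N/P/S exchange classes: two usable carbon sources (the
    second twice as substrate-rich) and one without a transporter."""
    spec = TOYEC1.with_(
        with_nutrient_classes=True,
        carbon_sources=(CarbonSource("C1"),
                        CarbonSource("C2", substrate_yield=2.0),
                        CarbonSource("C3", transportable=False)))
    ec, proteins = make_toy_ecgem(spec)
    return build_acidfba(ec, build_xi(proteins)), spec


@pytest.fixture
def rng():
    return np.random.default_rng(20_220_822)
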