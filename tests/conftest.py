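import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from desle import (
    BinarySystem,
    GeneratorSpec,
    MeltingProperties,
    RKCoefficients,
    simulate_sle_dataset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def walden_system():
    """600 K / 300 K ideal pair, both enthalpies from the Walden rule."""
    return BinarySystem(
        props1=MeltingProperties(Tm=600.0, dHm=32_640.0),
        props2=MeltingProperties(Tm=300.0, dHm=16_320.0),
    )


@pytest.fixture
def symmetric_system():
    """Identical melting properties on both sides, both branches ideal."""
    props = MeltingProperties(Tm=400.0, dHm=20_000.0)
    return BinarySystem(props1=props, props2=props)


@pytest.fixture
def salt_screening_dataset():
    """Noiseless branch-1 solubility of a low-enthalpy, high-melting salt
    (597 K, 5 kJ/mol — choline-chloride-like) in a Walden-rule partner,
    sampled on the salt-rich side x1 in [0.5, 0.99]."""
    system = BinarySystem(
        props1=MeltingProperties(Tm=597.0, dHm=5_000.0),
        props2=MeltingProperties(Tm=330.0, dHm=54.4 * 330.0),
        name1="salt",
        name2="partner",
    )
    spec = GeneratorSpec(
        system=system,
        seed=3,
        n_per_branch=25,
        sigma_T=0.0,
        branches=(1,),
        x1_range_branch1=(0.5, 0.99),
    )
    return simulate_sle_dataset(spec), system
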