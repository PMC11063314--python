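import numpy as np
import pytest

from ofsca import ComponentSpec, generate_trial


@pytest.fixture(scope="session")
def standard_trial():
    """One default-geometry trial: H1=0.9 AP-aligned, H2=0.6 ML-aligned."""
    return generate_trial(
        ComponentSpec(hurst=0.9, angle_deg=90.0),
        ComponentSpec(hurst=0.6, angle_deg=0.0),
        seed=12345,
    )


@pytest.fixture(scope="session")
def oblique_trial():
    """A suborthogonal trial with component axes 60 degrees apart."""
    return generate_trial(
        ComponentSpec(hurst=0.9, angle_deg=90.0),
        ComponentSpec(hurst=0.6, angle_deg=30.0),
        seed=999,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
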