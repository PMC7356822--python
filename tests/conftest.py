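import numpy as np
import pytest

from synthmri.synthetic_data import (
    BrainPhantomSpec,
    PhantomSpec,
    build_brain_phantom,
    build_cylinder_phantom,
    calibrate_relaxivity,
    default_tube_ring,
    load_phantom_reference_table,
)


@pytest.fixture(scope="session")
def reference_table():
    return load_phantom_reference_table()


@pytest.fixture(scope="session")
def relaxivity_model(reference_table):
    return calibrate_relaxivity(reference_table)


@pytest.fixture(scope="session")
def small_t1_phantom(relaxivity_model):
    """Seven-tube T1 phantom on a coarse grid (fast to fit)."""
    spec = PhantomSpec(
        tubes=default_tube_ring((1.0, 0.8, 0.7, 0.6, 0.5, 0.4, 0.2)),
        shape=(48, 48, 6),
    )
    return build_cylinder_phantom(spec, relaxivity_model)


@pytest.fixture(scope="session")
def brain_maps():
    return build_brain_phantom(BrainPhantomSpec())
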