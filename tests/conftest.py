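import numpy as np
import pytest

from hingemount import FacebowSpec, default_generator_spec, generate_cohort

# Fixture facebow dimensions: a plausible nasal-support height with the hinge
# axis at the AOP anchor. These exercise the geometry; they are not claimed to
# be the dimensions of any commercial facebow.
FIXTURE_FACEBOW = FacebowSpec(d_ns_mm=23.0, ax_offset_along_mm=0.0, ax_offset_perp_mm=0.0)


@pytest.fixture(scope="session")
def facebow() -> FacebowSpec:
    return FIXTURE_FACEBOW


@pytest.fixture(scope="session")
def default_cohort():
    """The 514-patient three-phenotype mixture at the default seed."""
    return generate_cohort(default_generator_spec())


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
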