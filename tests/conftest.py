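import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import twinconn as tc
from twinconn.simulate import design_matrix


@pytest.fixture(scope="session")
def study_cohort():
    """Cohort at the study's sample size: 123 MZ + 67 DZ pairs."""
    return tc.generate_pedigree(123, 67, seed=11)


@pytest.fixture(scope="session")
def study_design(study_cohort):
    return design_matrix(study_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    return tc.generate_pedigree(6, 4, seed=5)


@pytest.fixture(scope="session")
def area_levels():
    """Levels of the packaged left hemisphere (24 areas, eta 0-10)."""
    edges = tc.visual_area_graph(("L",))
    from twinconn.hierarchy import levels_table

    return levels_table(edges, roots=("L_V1",)).set_index("area")["eta"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
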