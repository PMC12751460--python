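import numpy as np
import pytest

from nestmove.io import ArenaGeometry
from nestmove.pipeline import StudyConfig, run_pipeline
from nestmove.synthetic import default_cohort_spec


@pytest.fixture(scope="session")
def arena():
    return ArenaGeometry()


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Scaled-down study design: 5 species x 2 colonies x 2 workers, 5 min."""
    return default_cohort_spec(
        duration_s=300.0, colonies_per_species=2, individuals_per_colony=2, seed=7
    )


@pytest.fixture(scope="session")
def small_pipeline_result(small_cohort_spec):
    return run_pipeline(StudyConfig(cohort=small_cohort_spec, fit_models=False), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
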