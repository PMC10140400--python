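import logging

import numpy as np
import pytest

from burnoutnet import (
    SimulationConfig,
    SurveySchema,
    VariableSpec,
    cohort_effect_sizes,
    default_schema,
    generate_survey,
)

# expected-count warnings from sparse synthetic draws are noise in test logs
logging.getLogger("burnoutnet.screen").setLevel(logging.ERROR)
logging.getLogger("burnoutnet.codec").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_schema():
    """Compact four-category schema for fast simulation tests."""
    return SurveySchema(variables=[
        VariableSpec("Age", "demographic", "numeric", range=(18.0, 60.0),
                     loc=33.0, scale=10.0),
        VariableSpec("Sex", "demographic", "binary", levels=("Female", "Male"),
                     level_probs=(0.4, 0.6)),
        VariableSpec("Position", "work_related", "nominal",
                     levels=("Management", "Technician", "Assistant"),
                     level_probs=(0.1, 0.6, 0.3)),
        VariableSpec("Health", "health", "ordinal",
                     levels=("Healthy", "Sub-health", "Unhealthy"),
                     level_probs=(0.5, 0.4, 0.1)),
        VariableSpec("Exercise", "lifestyle", "binary", levels=("Yes", "No"),
                     level_probs=(0.45, 0.55)),
    ])


@pytest.fixture(scope="session")
def cohort_survey(schema):
    """One medium synthetic cohort with the reference-cohort contrast."""
    config = SimulationConfig(
        n_respondents=1500, seed=20240901,
        effect_sizes=cohort_effect_sizes(schema))
    return generate_survey(schema, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
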