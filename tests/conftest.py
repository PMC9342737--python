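import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from partworth import (
    AttributeSpec,
    enumerate_full_factorial,
    least_fill_assign,
    search_fractional_design,
    simulate_survey,
    study_template,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """(attrs, model) for the six-attribute clinical vignette template."""
    return study_template()


@pytest.fixture(scope="session")
def study_catalog(study):
    attrs, _ = study
    return enumerate_full_factorial(attrs)


@pytest.fixture(scope="session")
def study_design(study, study_catalog):
    """A searched 42-profile fractional design (few restarts: test speed)."""
    attrs, _ = study
    return search_fractional_design(study_catalog, attrs, 42, restarts=5, seed=11)


@pytest.fixture(scope="session")
def study_plan(study_design):
    return least_fill_assign(
        [p.profile_id for p in study_design.profiles], 400, 8, seed=12
    )


@pytest.fixture(scope="session")
def study_responses(study, study_design, study_plan):
    attrs, model = study
    return simulate_survey(model, study_plan, study_design.profiles, attrs, seed=13)


@pytest.fixture
def small_attrs():
    """A tiny two-attribute spec for closed-form and brute-force checks."""
    return [
        AttributeSpec("drug", ("A", "B")),
        AttributeSpec("dose", ("low", "mid", "high")),
    ]
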