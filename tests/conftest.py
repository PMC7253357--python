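import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from genemeta import load_fixture  # noqa: E402
from genemeta.effect_pooling import CorrectionPolicy, study_effect  # noqa: E402
from genemeta.genetic_models import (  # noqa: E402
    GeneticModel,
    PhenotypeContrast,
    build_contingency,
)

#: Sample sizes printed alongside the eight cohorts.
FIXTURE_TOTALS = {
    "Lang2007": 253, "Wang2007": 149, "Montag2008": 554, "Landi2009": 2238,
    "Zhang2012": 628, "Zhang2015": 1318, "JiangEA2017": 1616, "JiangAA2017": 3404,
}


@pytest.fixture(scope="session")
def fixture_set():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_tables(fixture_set):
    return [
        build_contingency(s, GeneticModel.DOMINANT, PhenotypeContrast.PERSISTENCE)
        for s in fixture_set
    ]


@pytest.fixture(scope="session")
def fixture_effects(fixture_tables):
    return [study_effect(t, CorrectionPolicy.ADD_HALF_IF_ZERO)
            for t in fixture_tables]


@pytest.fixture(scope="session")
def asian_effects(fixture_set):
    subset = fixture_set.filter(ancestry="Asian")
    return [
        study_effect(build_contingency(s, GeneticModel.DOMINANT,
                                       PhenotypeContrast.PERSISTENCE))
        for s in subset
    ]
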