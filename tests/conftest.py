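import pytest
from hypothesis import HealthCheck, settings

from madmsg import fixtures, madm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture():
    """The bundled reference decision matrix plus published total ranks."""
    return fixtures.paper_fixture()


@pytest.fixture(scope="session")
def rank_matrix(fixture):
    return madm.compute_ranks(fixture.matrix)


@pytest.fixture(scope="session")
def preset_results(fixture):
    """The four preset scenarios, with the published lab total-rank column
    substituted where a scenario consumes a study total (reproduction mode)."""
    presets = madm.preset_scenarios(fixture.matrix)
    results = madm.evaluate_scenarios(
        fixture.matrix,
        presets,
        total_rank_override={madm.LAB: fixture.published_lab_total_rank},
    )
    return presets, results
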