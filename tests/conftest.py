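import pytest

import scpbpk as s


@pytest.fixture(scope="session")
def base_scenario() -> s.ScenarioSpec:
    """Reference scenario: 10 mg IgG into the arm, calibrated defaults."""
    return s.ScenarioSpec()


@pytest.fixture(scope="session")
def base_result(base_scenario):
    """The reference simulation, shared across the suite (it is pure)."""
    return s.simulate(base_scenario)


@pytest.fixture(scope="session")
def base_model(base_result):
    return base_result.model


def run(scenario=None, **kwargs):
    """Convenience wrapper for one-off simulations in tests."""
    scenario = scenario or s.ScenarioSpec(**kwargs)
    return s.simulate(scenario)
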