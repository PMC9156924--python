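import pytest
from hypothesis import settings

import broilerland as bl

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> bl.ParameterSet:
    return bl.load_parameters()


@pytest.fixture(scope="session")
def baseline(params) -> bl.NationalBaseline:
    return params.baseline


@pytest.fixture(scope="session")
def feed_model(params) -> bl.FeedModel:
    return params.feed_model


@pytest.fixture(scope="session")
def breeds(params) -> dict[str, bl.BreedSpec]:
    return {b.name: b for b in params.breeds}


@pytest.fixture(scope="session")
def managements(params) -> dict[bl.ManagementKind, bl.ManagementSpec]:
    return {m.kind: m for m in params.managements}


@pytest.fixture(scope="session")
def land_cap(params) -> float:
    """Total conventional Ross-in-CAFO land, the cap for every scenario."""
    return bl.baseline_footprint(
        params.baseline, params.breeds, params.feed_model, params.managements
    ).total
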