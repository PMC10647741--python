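import pytest

from nloswitch.property_oracle import (
    SwitchEvaluator,
    SyntheticOracle,
    build_fixture_db,
    fixture_landscape_26r,
    fixture_printed_metrics,
)
from nloswitch.scaffold_space import hexaphyrin_scaffold, toy_scaffold


@pytest.fixture(scope="session")
def scaffold_26r():
    return hexaphyrin_scaffold("26R")


@pytest.fixture(scope="session")
def scaffold_30r():
    return hexaphyrin_scaffold("30R")


@pytest.fixture(scope="session")
def scaffold_three_state():
    return hexaphyrin_scaffold("three_state")


@pytest.fixture(scope="session")
def small_scaffold():
    # 3 sites x 4 fragments = 64 patterns: cheap to enumerate exhaustively
    return toy_scaffold(3, ("H", "OH", "NH2", "CN"))


@pytest.fixture(scope="session")
def fixture_db():
    return build_fixture_db()


@pytest.fixture(scope="session")
def printed_tables():
    return fixture_printed_metrics()


@pytest.fixture()
def fixture_oracle_26r():
    spec, scaffold = fixture_landscape_26r()
    return SyntheticOracle(spec, scaffold), scaffold


@pytest.fixture()
def fixture_evaluator_26r(fixture_oracle_26r):
    oracle, scaffold = fixture_oracle_26r
    return SwitchEvaluator(oracle, scaffold, metric="revised")
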