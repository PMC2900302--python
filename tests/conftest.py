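import pytest

from lineagetf import (
    ADIPOCYTE,
    OSTEOBLAST,
    build_reference_fixture,
    classify_all,
    compute_ratios,
)


@pytest.fixture(scope="session")
def fixture_dataset():
    return build_reference_fixture()


@pytest.fixture(scope="session")
def fixture_tables(fixture_dataset):
    return {
        lineage: compute_ratios(
            fixture_dataset.expression, fixture_dataset.metadata, lineage
        )
        for lineage in (OSTEOBLAST, ADIPOCYTE)
    }


@pytest.fixture(scope="session")
def fixture_calls(fixture_tables):
    return {lineage: classify_all(table) for lineage, table in fixture_tables.items()}
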