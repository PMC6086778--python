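import pytest

from chemstd.fixtures import paper_fixtures, random_corpus
from chemstd.pipeline import Standardizer


@pytest.fixture(scope="session")
def standardizer():
    return Standardizer()


@pytest.fixture(scope="session")
def corpus():
    """Small seeded corpus shared by the property tests."""
    return random_corpus(seed=1, n=40, max_heavy=12)


@pytest.fixture(scope="session")
def fixture_cases():
    return paper_fixtures()


@pytest.fixture(scope="session")
def fixture_results(standardizer, fixture_cases):
    """Each fixture case standardized once (cached for the whole session)."""
    return [(case, standardizer.standardize(case.molecule()))
            for case in fixture_cases]
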