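import pytest

from acedup.allele_model import PhenotypeClass, canonical_model

from acedup.pipeline import get_sample, pool_d1, table1_fixture

P = PhenotypeClass.parse


@pytest.fixture(scope="session")
def samples5():
    """The six packaged five-class phenotype count samples."""
    return table1_fixture()


@pytest.fixture(scope="session")
def samples3(samples5):
    """The same samples pooled to the three-class partition."""
    return [pool_d1(t) for t in samples5]


@pytest.fixture(scope="session")
def yop15_3(samples3):
    return next(t for t in samples3 if t.population == "Yopougon" and t.year == 2015)


@pytest.fixture(scope="session")
def yop15_5(samples5):
    return get_sample(samples5, "Yopougon", 2015)


@pytest.fixture(scope="session")
def yop12_3(samples3):
    return next(t for t in samples3 if t.population == "Yopougon" and t.year == 2012)


@pytest.fixture(scope="session")
def model_a():
    return canonical_model("A")


@pytest.fixture(scope="session")
def model_b():
    return canonical_model("B")


@pytest.fixture(scope="session")
def model_c():
    return canonical_model("C")
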