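import pytest

from psidrift import CategoryCountVector, load_seer_table1


@pytest.fixture(scope="session")
def table1():
    """Packaged SEER count vectors, one per (variable, year)."""
    return load_seer_table1()


@pytest.fixture(scope="session")
def age_by_year(table1):
    return {v.sample_id: v for v in table1 if v.variable_name == "age_group"}


@pytest.fixture(scope="session")
def by_variable(table1):
    out = {}
    for v in table1:
        out.setdefault(v.variable_name, []).append(v)
    return out


def make_vector(counts, variable="x", sample="s", categories=None):
    categories = categories or tuple(f"c{i}" for i in range(len(counts)))
    return CategoryCountVector(
        variable_name=variable,
        sample_id=sample,
        categories=tuple(categories),
        counts=tuple(counts),
    )


@pytest.fixture
def vec():
    return make_vector
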