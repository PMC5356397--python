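import pytest

from pedseg import (
    assign_phenotypes,
    filter_evaluable,
    load_cohort_k,
    load_cohort_t,
    load_onset_table,
)


@pytest.fixture(scope="session")
def onset_table():
    return load_onset_table()


def _prepared(pedigree):
    phenotypes = assign_phenotypes(pedigree)
    usable = filter_evaluable(pedigree, phenotypes)
    return usable, {d: phenotypes[d] for d in usable.dogs}


@pytest.fixture(scope="session")
def cohort_k_full():
    return load_cohort_k()


@pytest.fixture(scope="session")
def cohort_t_full():
    return load_cohort_t()


@pytest.fixture(scope="session")
def cohort_k(cohort_k_full):
    """(usable pedigree, phenotypes) for family K."""
    return _prepared(cohort_k_full)


@pytest.fixture(scope="session")
def cohort_t(cohort_t_full):
    """(usable pedigree, phenotypes) for family T."""
    return _prepared(cohort_t_full)
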