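import numpy as np
import pytest

import pedscore as ps


@pytest.fixture(scope="session")
def family():
    return ps.canonical_family()


@pytest.fixture(scope="session")
def family_phi(family):
    return ps.kinship_matrix(family)


@pytest.fixture(scope="session")
def cohort():
    return ps.canonical_cohort(10)


@pytest.fixture(scope="session")
def cohort_phi(cohort):
    return ps.kinship_matrix(cohort)


@pytest.fixture(scope="session")
def small_dataset(cohort, cohort_phi):
    """A 60-SNP null dataset on the full 100-individual cohort."""
    params = ps.SimParams(n_snps=60, seed=11)
    return ps.simulate_dataset(cohort, params, phi=cohort_phi)


@pytest.fixture(scope="session")
def small_scan(small_dataset, cohort, cohort_phi):
    return ps.genome_scan(small_dataset, phi=cohort_phi, ped=cohort)
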