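"""Shared fixtures: a high-information population model and small hand tables."""
import numpy as np
import pytest

from colonykin import GenotypeTable, make_population_model


@pytest.fixture(scope="session")
def model12x20():
    """12 loci x 20 equifrequent alleles, single site: the reference design."""
    return make_population_model(n_loci=12, alleles_per_locus=20, seed=11)


@pytest.fixture(scope="session")
def true_freqs(model12x20):
    return model12x20.allele_frequencies(0)


def make_table(rows, loci):
    """rows: (id, colony, site, caste, ploidy, {locus: call}) tuples."""
    return GenotypeTable.from_records(rows, loci=loci)


@pytest.fixture
def worker_row():
    def _row(ind, colony, calls, site="K", caste="worker", ploidy=2):
        return (ind, colony, site, caste, ploidy, calls)

    return _row
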