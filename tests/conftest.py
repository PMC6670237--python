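import numpy as np
import pandas as pd
import pytest

from mammotype import synthetic


@pytest.fixture(scope="session")
def config():
    """Default study-shaped cohort config (9 subtypes x 2 tumors)."""
    return synthetic.SyntheticCohortConfig(seed=11)


@pytest.fixture(scope="session")
def small_config():
    """Small, fast cohort for pipeline tests."""
    return synthetic.SyntheticCohortConfig(
        seed=13, n_genes=200, n_mutations_per_tumor=100, n_cna_genes=300
    )


@pytest.fixture(scope="session")
def expression_cohort(small_config):
    return synthetic.generate_expression_cohort(small_config)


@pytest.fixture(scope="session")
def reference_signatures():
    return synthetic.generate_signature_matrix(n_signatures=4, seed=21)


@pytest.fixture(scope="session")
def census():
    return synthetic.generate_census(n_genes=20, seed=23)


@pytest.fixture(scope="session")
def variant_cohort(small_config, reference_signatures, census):
    records, snp_sites = synthetic.generate_variant_table(
        small_config, reference_signatures, census["gene"]
    )
    return records, snp_sites


@pytest.fixture(scope="session")
def cna_cohort(small_config, census):
    return synthetic.generate_cna_profiles(small_config, census)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_variant_row(**overrides):
    """One well-formed passing variant record, overridable per test."""
    row = {
        "tumor_id": "t1", "chrom": "chr1", "pos": 100,
        "ref_allele": "C", "alt_allele": "A",
        "total_depth": 100, "alt_depth": 20, "alt_forward": 10, "alt_reverse": 10,
        "caller_pass": True, "gene": "Trp53", "impact": "MODERATE",
        "aa_change": "", "trinucleotide": "ACA",
    }
    row.update(overrides)
    return row


def variant_frame(rows):
    return pd.DataFrame(rows)
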