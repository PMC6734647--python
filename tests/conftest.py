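import numpy as np
import pytest

from syncrc.cohort import CohortTable
from syncrc.io import data_path
from syncrc.records import VariantRecord
from syncrc.synthetic import SimulationConfig, simulate_cohort


def mk_snv(
    sample="t1",
    contig="chr1",
    pos=100,
    ref="C",
    alt="T",
    depth=50,
    alt_depth=20,
    qual=40.0,
    flank5="A",
    flank3="A",
    gene=None,
    consequence="missense",
    coding=True,
):
    return VariantRecord(
        sample_id=sample,
        contig=contig,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        variant_class="SNV",
        total_depth=depth,
        alt_depth=alt_depth,
        quality=qual,
        flank5=flank5,
        flank3=flank3,
        gene=gene,
        consequence=consequence,
        coding=coding,
    )


def mk_indel(
    sample="t1",
    contig="chr1",
    pos=200,
    ref="A",
    alt="AT",
    depth=50,
    alt_depth=10,
    qual=40.0,
    gene=None,
    consequence="frameshift",
    coding=True,
):
    return VariantRecord(
        sample_id=sample,
        contig=contig,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        variant_class="indel",
        total_depth=depth,
        alt_depth=alt_depth,
        quality=qual,
        gene=gene,
        consequence=consequence,
        coding=coding,
    )


@pytest.fixture(scope="session")
def cohort_fixture():
    return CohortTable.read_tsv(data_path("cohort_metadata.tsv"))


@pytest.fixture(scope="session")
def small_sim():
    """Six-patient synthetic cohort shared across tests (read-only)."""
    return simulate_cohort(
        SimulationConfig(
            n_patients=6,
            seed=20_19,
            pair_mmr_probs={"MSS-MSS": 0.5, "MSI-MSI": 0.3, "MSS-MSI": 0.2},
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
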