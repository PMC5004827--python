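import logging

import pytest

from matriline import (
    AlignedSequenceSet,
    SampleMetadata,
    SampleRecord,
    collapse_haplotypes,
    make_fixture,
)

logging.disable(logging.WARNING)


def make_alignment(seq_by_id: dict) -> AlignedSequenceSet:
    return AlignedSequenceSet(
        ids=tuple(seq_by_id), seqs=tuple(seq_by_id.values()),
        filter_mode="complete_deletion",
    )


def make_meta(species_by_id: dict) -> SampleMetadata:
    return SampleMetadata(
        SampleRecord(individual_id=i, species=sp) for i, sp in species_by_id.items()
    )


@pytest.fixture(scope="session")
def two_species():
    """Clean two-species dataset (alignment, metadata, truth)."""
    return make_fixture("two_species_clean")


@pytest.fixture(scope="session")
def radiation():
    """Six-species radiation, 118 individuals, no introgression."""
    return make_fixture("six_species_radiation")


@pytest.fixture(scope="session")
def introgression():
    """Six-species radiation with 6 planted introgressed individuals."""
    return make_fixture("introgression_6")


@pytest.fixture(scope="session")
def introgression_analysis(introgression):
    """Haplotype table, MJ network and NJ tree for the introgression fixture."""
    from matriline import distance_matrix, median_join, nj_tree

    alignment, metadata, truth = introgression
    table = collapse_haplotypes(alignment)
    network = median_join(table, metadata=metadata)
    tree = nj_tree(distance_matrix(table.to_alignment()))
    return table, network, tree
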