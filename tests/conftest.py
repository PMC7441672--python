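import pytest

from ocpmd.synthetic import (
    CohortConfig,
    GeneForgeConfig,
    forge_gene_model,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def forged_default():
    """The TNNT1-like default gene: donor of intron 13 at c.614+1."""
    return forge_gene_model(GeneForgeConfig())


@pytest.fixture(scope="session")
def forged_codon_boundary():
    """Variant configuration with the retention junction on a codon boundary.

    Places the intron-13 donor at c.747+1 so the retained-intron protein
    reproduces the published tail accounting: 263 -> 261 residues, the
    terminal 14 replaced by 12 intron-encoded residues.
    """
    return forge_gene_model(GeneForgeConfig(donor_cds_position=747))


@pytest.fixture(scope="session")
def forged_small():
    """A compact forged gene on a short contig for fast I/O tests."""
    return forge_gene_model(
        GeneForgeConfig(contig_length=20_000, intron_lengths=(50,) * 12 + (810, 50))
    )


@pytest.fixture(scope="session")
def default_cohort(forged_default):
    return simulate_cohort(forged_default, CohortConfig(seed=11))
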