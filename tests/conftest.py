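"""Shared fixtures: small seeded genomes and read sets built at test time."""

import pytest

from isomito.synthetic import (
    GenomeModel,
    HeteroplasmySpec,
    ReadSimParams,
    generate_monomer,
    plant_heteroplasmies,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    """4-kb featureless monomer with 25+4 bp hairpin termini."""
    return generate_monomer(4000, 25, 4, None, seed=42)


def _alt(base: str) -> str:
    return "A" if base != "A" else "C"


@pytest.fixture(scope="session")
def linked_genome(small_genome) -> GenomeModel:
    """Two linked substitution heteroplasmies 400 bp apart at frequency 0.5."""
    s = small_genome.monomer_seq
    specs = [
        HeteroplasmySpec(1600, s[1599], _alt(s[1599]), 0.5, "H1"),
        HeteroplasmySpec(2000, s[1999], _alt(s[1999]), 0.5, "H1"),
    ]
    return plant_heteroplasmies(small_genome, specs)


@pytest.fixture(scope="session")
def linked_sim(linked_genome):
    """Error-free monomer-only reads from the linked two-haplotype genome."""
    params = ReadSimParams(coverage=120, read_len=100, insert_mean=500,
                           insert_sd=40, sub_error_rate=0.0,
                           dimer_fraction=0.0, seed=7)
    return simulate_reads(linked_genome, params)
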