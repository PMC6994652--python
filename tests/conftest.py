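"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from mobigraft import GeneModel, GenomeSequence, SimulationConfig, simulate_experiment
from mobigraft.graftsim import _random_sequence


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome() -> GenomeSequence:
    return GenomeSequence(
        name="toy",
        contigs={"chr1": "ACGTACGTGGCCAATTACGT", "chr2": "TTTTACGTACGTAAAA"},
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study: one 50 kb contig per species, 30 genes, 5 mobile."""
    return SimulationConfig(
        seed=20, n_contigs=1, contig_length=50_000, n_genes=30,
        genotype_snps=60, genotype_insertions=8, genotype_deletions=8,
        genotype_segment_count=1, genotype_segment_length=500,
        fragments_per_library=3_000, mobile_per_direction=5,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture
def random_genome(rng) -> GenomeSequence:
    return GenomeSequence(name="rand", contigs={"c1": _random_sequence(rng, 20_000)})


def make_gene(gene_id: str, contig: str, exons, strand: str = "+") -> GeneModel:
    return GeneModel(gene_id=gene_id, contig=contig, strand=strand, exons=exons)
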