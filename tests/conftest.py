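"""Shared fixtures: small seeded synthetic datasets, generated at test time."""

from __future__ import annotations

import pytest
from hypothesis import settings

from pirnakit import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_spec() -> synthetic.SyntheticSpec:
    """A fast, fully-featured simulation: clusters, repeats, ncRNA, genes."""
    return synthetic.SyntheticSpec(
        genome_length=200_000,
        n_chromosomes=2,
        n_clusters=4,
        cluster_length_range=(5000, 9000),
        reads_per_cluster=150,
        reads_per_repeat_copy=10,
        background_reads=200,
        ncrna_contaminant_fraction=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """(spec, genome, truth, fastq records, origin table) for the small spec."""
    genome, truth = synthetic.simulate_genome(small_spec)
    reads, origin = synthetic.simulate_reads(small_spec, genome, truth)
    return small_spec, genome, truth, reads, origin
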