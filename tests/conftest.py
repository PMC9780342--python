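"""Shared fixtures: one toy genome/vector and a mid-size classified library.

Everything is generated programmatically; session scope keeps the slower
pipeline runs to one execution each.
"""

import pytest
from hypothesis import settings

import pemseq as pq
from pemseq.simulate import default_config, simulate_library

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def genome():
    return pq.build_toy_genome(seed=1)


@pytest.fixture(scope="session")
def vector():
    return pq.build_vector(seed=1)


@pytest.fixture(scope="session")
def genome_index(genome):
    return pq.ReferenceIndex(genome.chromosomes)


@pytest.fixture(scope="session")
def vector_index(vector):
    return pq.ReferenceIndex({"vector": vector.sequence})


@pytest.fixture(scope="session")
def clean_library(genome, vector):
    """Error-free mixed library, 2,500 molecules with PCR duplication."""
    cfg = default_config(seed=42, n_molecules=2_500, error_rate=0.0)
    reads, truth = simulate_library(genome, vector, cfg)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def clean_run(genome, vector, clean_library):
    """Pipeline result on the clean library with known off-target cuts."""
    _, reads, _ = clean_library
    return pq.run_pipeline(reads, genome, vector, known_offtargets=genome.offtarget_cut_sites())
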