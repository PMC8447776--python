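"""Shared fixtures: small synthetic genomes with planted structure.

Everything is generated at test time from fixed seeds; session scope keeps
the heavier contact simulations shared across test modules.
"""

import numpy as np
import pytest

from chromhier import (make_genome, plant_truth, simulate_contacts,
                       simulate_annotation_and_expression, ice_balance)


@pytest.fixture(scope="session")
def small_genome():
    """Two micro-chromosomes of ~11 Mb."""
    return make_genome(0, 2, None, (10_000_000, 12_000_000), seed=1)


@pytest.fixture(scope="session")
def truth(small_genome):
    return plant_truth(small_genome, comp_block_bp=1_000_000,
                       n_boundaries_per_chrom=6, n_loops=20,
                       max_loop_span=1_000_000, seed=2)


@pytest.fixture(scope="session")
def genes_expr(small_genome, truth):
    return simulate_annotation_and_expression(small_genome, truth, seed=4)


@pytest.fixture(scope="session")
def cmap_100k(small_genome, truth):
    """Compartment-scale map: 100 kb bins, depth 1e7."""
    return simulate_contacts(small_genome, truth, resolution=100_000,
                             depth=1e7, seed=3)


@pytest.fixture(scope="session")
def balanced_100k(cmap_100k):
    return {c: ice_balance(cmap_100k.chrom_dense(c))
            for c in cmap_100k.genome.names}


@pytest.fixture(scope="session")
def tad_genome():
    """Three micro-chromosomes for 10 kb-scale TAD/loop work."""
    return make_genome(0, 3, None, (8_000_000, 12_000_000), seed=7)


@pytest.fixture(scope="session")
def tad_truth(tad_genome):
    return plant_truth(tad_genome, comp_block_bp=1_000_000,
                       n_boundaries_per_chrom=8, n_loops=50,
                       max_loop_span=1_000_000, seed=7)


@pytest.fixture(scope="session")
def cmap_10k(tad_genome, tad_truth):
    """Full-structure 10 kb map, depth 1e7."""
    return simulate_contacts(tad_genome, tad_truth, resolution=10_000,
                             depth=1e7, seed=7)


@pytest.fixture(scope="session")
def balanced_10k(cmap_10k):
    return {c: ice_balance(cmap_10k.chrom_dense(c))
            for c in cmap_10k.genome.names}
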