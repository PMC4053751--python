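"""Shared fixtures: small deterministic genomes and read sets.

Everything is generated at runtime from fixed seeds — no stored fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import haplasm as H

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """20 kbp repeat-free diploid genome, no variants."""
    return H.gen_diploid_genome(20_000, seed=101)


@pytest.fixture(scope="session")
def small_reads(small_truth):
    """Error-free depth-40 haploid paired-end reads from small_truth."""
    return H.sim_reads(small_truth, "paired_end", depth=40, read_len=100,
                       insert_mean=300, insert_sd=25, error_rate=0.0,
                       source="haploid", seed=101)


@pytest.fixture(scope="session")
def small_db(small_reads):
    db = H.count_kmers(small_reads, k=21)
    db.solid_threshold = H.suggest_solid_threshold(db)
    return db


@pytest.fixture(scope="session")
def small_assembly(small_reads):
    """Assembled contigs for the clean 20 kbp read set."""
    return H.haploid_assemble(small_reads, k=21)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
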