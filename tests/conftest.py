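import dataclasses

import numpy as np
import pytest

from mdagenome.records import ReadSet, SequenceRecord
from mdagenome.simulate import (
    CommunitySpec,
    GenomeSpec,
    ReadModel,
    bulk_bias_profile,
    pure_target_community,
    simulate_genome,
    simulate_reads,
)

BASES = np.array(list("ACGT"))


def random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def random_records(n: int, rng: np.random.Generator, min_len=30, max_len=200):
    out = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len))
        qual = rng.integers(0, 42, L).astype(np.int16)
        out.append(SequenceRecord(f"r{i:04d}", random_seq(L, rng), qual))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_target_spec():
    return GenomeSpec("target", 50_000, 0.324, seed=0)


@pytest.fixture(scope="session")
def small_target(small_target_spec):
    return simulate_genome(small_target_spec)


@pytest.fixture(scope="session")
def cell_sample(small_target_spec, small_target):
    """A pure single-cell-like sample with gentle (bulk) bias: 20x over a
    50 kb genome, 2% chimeras — shared across mapping/filter tests."""
    community = CommunitySpec(small_target_spec, (), 1.0)
    profile = bulk_bias_profile(small_target_spec.length, seed=3)
    return simulate_reads(
        community,
        {"target": profile},
        2500,
        ReadModel(chimera_rate=0.02),
        seed=7,
        genomes={"target": small_target},
    )
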