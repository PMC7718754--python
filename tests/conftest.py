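"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from repeatscape.readcluster import Read
from repeatscape.synthio import (
    ClockModel,
    SpeciesProfile,
    TEFamilySpec,
    simulate_family_library,
    simulate_genome,
    simulate_reads,
)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutated(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute the given positions with a different base each."""
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return "".join(out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_families():
    return simulate_family_library(
        3, seed=101, ltr_len_range=(250, 300), internal_len_range=(800, 900),
        target_mb_range=(0.05, 0.06), age_my_range=(0.8, 1.2),
    )


@pytest.fixture(scope="session")
def small_sim(small_families):
    """A 0.3 Mb single-species genome with three planted families."""
    profile = SpeciesProfile("spT", 0.3, small_families, gene_count=20)
    return simulate_genome(
        profile, ClockModel(), seed=202, upstream_fraction=0.25, upstream_range=(1, 2000)
    )


@pytest.fixture(scope="session")
def small_reads(small_sim):
    reads, _ = simulate_reads(small_sim, coverage=0.4, read_len=100, error_rate=0.002, seed=303)
    return [Read(rid, "spT", seq) for rid, seq in reads]


def planted_cluster_fixture(seed: int = 7, n_random: int = 4, copies=(3, 3), divergence=0.03):
    """Reads from ``len(copies)`` unrelated repeat templates plus random singletons.

    Each template contributes ``copies[i]`` mutated full-length copies
    (mutual identity ~1 - 2*divergence), guaranteed mutually >= 90%
    similar for divergence <= 0.04.
    """
    gen = np.random.default_rng(seed)
    reads = []
    for t, n_copies in enumerate(copies):
        template = random_dna(gen, 120)
        for c in range(n_copies):
            n_mut = gen.binomial(len(template), divergence)
            positions = gen.choice(len(template), size=n_mut, replace=False)
            reads.append(Read(f"t{t}_c{c}", "spT", mutated(template, positions, gen)))
    for i in range(n_random):
        reads.append(Read(f"rand_{i}", "spT", random_dna(gen, 110)))
    return reads
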