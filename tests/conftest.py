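"""Shared fixtures: tiny hand-built objects plus one module-scoped simulated
study that several test modules reuse."""

from __future__ import annotations

import numpy as np
import pytest

from tnsight.calling import InsertionLibrary
from tnsight.genome import Genome, ORFRecord
from tnsight.simulate import SimConfig, simulate_genome, simulate_library


@pytest.fixture
def tiny_genome() -> Genome:
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
    return Genome({"chrI": seq})


def make_library(records, **meta) -> InsertionLibrary:
    return InsertionLibrary.from_records(records, meta or None)


@pytest.fixture
def small_library() -> InsertionLibrary:
    return make_library(
        [("chrI", 100, 3), ("chrI", 250, 1), ("chrI", 900, 10), ("chrII", 5, 2)]
    )


@pytest.fixture(scope="module")
def sim_study():
    """A small but realistic simulated AcDs-like study (module-scoped)."""
    config = SimConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=100_000,
        n_orfs=90,
        n_insertions=20_000,
        jackpot_rate=0.0,
    )
    genome, orfs, truth = simulate_genome(config)
    lib, truth = simulate_library(genome, orfs, truth.labels, config)
    return {"config": config, "genome": genome, "orfs": orfs,
            "labels": truth.labels, "lib": lib, "truth": truth}
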