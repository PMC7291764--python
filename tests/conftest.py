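"""Shared fixtures: a seeded synthetic habitat, its training-set ladder and
a simulated read set, built once per session (several test modules and the
acceptance tests reuse them)."""

from __future__ import annotations

import pytest

from habitax import (
    BuildParams,
    SimParams,
    make_synthetic_habitat,
)
from habitax.workflow import build_training_sets, simulate_reads, sweep_datasets

SEED = 42


@pytest.fixture(scope="session")
def habitat():
    """Six genera x four species, ten variants each, one species pair forced
    identical over the sequenced sub-region."""
    return make_synthetic_habitat(
        n_genera=6, species_per_genus=4, variants_per_species=10,
        identical_region_pairs=1, rng_seed=SEED)


@pytest.fixture(scope="session")
def build_result(habitat):
    return build_training_sets(habitat.references, habitat.pool,
                               BuildParams(rng_seed=SEED))


@pytest.fixture(scope="session")
def reads(build_result):
    """500 error-bearing R2(250)-10N-R1(100) reads from the curated set."""
    return simulate_reads(build_result["region_curated"],
                          SimParams(error_rate=0.01, r2_len=250, r1_len=100,
                                    rng_seed=SEED), n_reads=500)


@pytest.fixture(scope="session")
def sweeps(build_result, reads):
    """Threshold sweeps (minBoot 50..100) for all five training sets."""
    return sweep_datasets(build_result.training_sets, reads, rng_seed=SEED)
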