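"""Shared fixtures: small synthetic cohorts reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from saccpop import snpcall, synthgen


@pytest.fixture(scope="session")
def small_spec():
    return synthgen.default_genome_spec(seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """4 wild + 4 domesticated isolates on a ~206 kb genome, depth 50."""
    params = synthgen.CohortParams(n_wild=4, n_domesticated=4,
                                   mean_depth=50.0, error_rate=0.002)
    return synthgen.simulate_cohort(small_spec, params, seed=7)


@pytest.fixture(scope="session")
def small_pileups(small_cohort):
    return small_cohort.pileups(seed=7)


@pytest.fixture(scope="session")
def small_calls(small_pileups):
    return {iid: snpcall.call_pileup(p) for iid, p in small_pileups.items()}


@pytest.fixture(scope="session")
def small_matrix(small_calls):
    return snpcall.build_matrix(small_calls)


def random_matrix(seed: int, n_isolates: int = 12, n_sites: int = 150,
                  het_fraction: float = 0.2, missing_fraction: float = 0.05,
                  ) -> snpcall.GenotypeMatrix:
    """An arbitrary IUPAC matrix for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    hets = np.array(list("RYSWKM"))
    calls = bases[rng.integers(0, 4, size=(n_isolates, n_sites))]
    het_mask = rng.random(calls.shape) < het_fraction
    calls[het_mask] = hets[rng.integers(0, 6, size=int(het_mask.sum()))]
    n_mask = rng.random(calls.shape) < missing_fraction
    calls[n_mask] = "N"
    return snpcall.GenotypeMatrix(
        [f"iso{i}" for i in range(n_isolates)],
        np.array(["chrI"] * n_sites),
        np.arange(1, n_sites + 1, dtype=np.int64),
        bases[rng.integers(0, 4, size=n_sites)],
        calls)
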