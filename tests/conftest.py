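"""Shared fixtures: small deterministic matrices and cheap simulations.

Everything is generated at test time; no data files are shipped.
"""

from __future__ import annotations

import numpy as np
import pytest

from sweepscan import (
    HaplotypeMatrix,
    PopulationMap,
    SimConfig,
    SweepConfig,
    simulate,
)


def random_matrix(
    rng: np.random.Generator,
    n_hap: int,
    n_var: int,
    chrom: str = "1",
    max_pos: int | None = None,
    missing_rate: float = 0.0,
) -> HaplotypeMatrix:
    """Random phased matrix with strictly increasing positions."""
    assert n_hap % 2 == 0
    max_pos = max_pos or n_var * 100
    positions = np.sort(rng.choice(np.arange(1, max_pos + 1), size=n_var, replace=False))
    alleles = rng.integers(0, 2, size=(n_hap, n_var)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(alleles.shape) < missing_rate
        alleles[mask] = -1
    return HaplotypeMatrix(
        chrom=chrom,
        positions=positions,
        alleles=alleles,
        sample_ids=[f"s{i}" for i in range(n_hap // 2)],
    )


@pytest.fixture(scope="session")
def small_sim():
    """Cheap two-population neutral simulation shared across tests."""
    cfg = SimConfig(
        seed=42,
        chrom_length=100_000,
        n_pops=2,
        pop_size=40,
        split_time=30,
        mu=6.25e-6,  # 4N*mu = 1e-3
        rec=2.5e-6,
        sample_sizes=(12, 12),
    )
    matrices, truth = simulate(cfg)
    return cfg, matrices, truth


@pytest.fixture(scope="session")
def small_sweep_sim():
    """Cheap sweep simulation with truth, shared across tests."""
    cfg = SimConfig(
        seed=7,
        chrom_length=150_000,
        n_pops=2,
        pop_size=50,
        split_time=60,
        mu=5e-6,
        rec=2e-6,
        sample_sizes=(15, 15),
        sweep=SweepConfig(
            pop=0, position=75_000, s=0.1, h=0.7,
            introduction_time=60, min_final_freq=0.6,
        ),
    )
    matrices, truth = simulate(cfg)
    return cfg, matrices, truth


@pytest.fixture(scope="session")
def small_popmap(small_sim):
    _, matrices, _ = small_sim
    return PopulationMap(
        {s: pop for pop, m in matrices.items() for s in m.sample_ids}
    )
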