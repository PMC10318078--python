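"""Shared fixtures: small simulated cohorts and hand-built matrices."""

from __future__ import annotations

import numpy as np
import pytest

import rohscan as r
from rohscan.genome import default_autosome_lengths_bp


@pytest.fixture(scope="session")
def small_cfg() -> r.SimConfig:
    """Desk-scale cohort: 10 dogs, 3 chromosomes, ~6k SNPs."""
    return r.SimConfig(
        n_dogs=10,
        chromosomes={"1": 40_000_000, "2": 30_000_000, "3": 20_000_000},
        segments_per_dog=3,
        seg_len_high_bp=8e6,
        shared_island=r.SharedIsland(chrom="2", start_bp=5_000_000,
                                     length_bp=1_500_000,
                                     carrier_fraction=0.6),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return r.simulate(small_cfg)


@pytest.fixture(scope="session")
def small_gm(small_sim):
    return small_sim[0]


def make_matrix(calls: np.ndarray, chrom: str = "1",
                positions: np.ndarray | None = None,
                chroms: np.ndarray | None = None) -> r.GenotypeMatrix:
    """Wrap a raw (n, m) int call array as a GenotypeMatrix; positions
    default to 10 kb spacing on one chromosome."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1, dtype=np.int64) * 10_000
    if chroms is None:
        chroms = np.array([chrom] * m, dtype=object)
    alleles = np.empty((m, 2), dtype=object)
    alleles[:] = ("A", "B")
    return r.GenotypeMatrix(
        individuals=[r.Individual(sample_id=f"S{i + 1}") for i in range(n)],
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        chroms=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        calls=calls,
    )
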