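"""Shared fixtures: small genotype panels, frequency tables and scenarios
generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from paleoadmix import fstats, genodata, simulate
from paleoadmix.genodata import (
    GenotypeMatrix,
    IndividualRecord,
    SnpRecord,
)


def make_snps(n, chrom="1", span_m=0.25, start=0.0, alleles=("A", "C")):
    """Evenly spaced sites on one chromosome."""
    return [
        SnpRecord(
            f"s{i}", chrom, start + span_m * i / max(n - 1, 1),
            int(1e6 * (i + 1)), alleles[0], alleles[1],
        )
        for i in range(n)
    ]


def random_matrix(n_sites=100, n_inds=10, seed=0, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    pairs = [("A", "C"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "A")]
    snps = []
    for i in range(n_sites):
        ref, alt = pairs[rng.integers(len(pairs))]
        snps.append(
            SnpRecord(f"s{i}", str(1 + i // max(n_sites // 2, 1)),
                      0.001 * i, 1000 * (i + 1), ref, alt)
        )
    inds = [
        IndividualRecord(f"i{j}", f"P{j % 3}", "U", pseudo_haploid=(j % 4 == 0))
        for j in range(n_inds)
    ]
    calls = rng.integers(0, 3, size=(n_sites, n_inds)).astype(np.int8)
    for j, ind in enumerate(inds):
        if ind.pseudo_haploid:
            calls[:, j] = np.where(calls[:, j] == 1, 2, calls[:, j])
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = genodata.MISSING
    return GenotypeMatrix(snps, inds, calls)


@pytest.fixture
def toy_matrix():
    return random_matrix(100, 10, seed=1)


@pytest.fixture
def freq_fixture_200():
    """200 sites, 4 populations, no missingness, blocks spanning 5 groups."""
    rng = np.random.default_rng(42)
    snps = make_snps(200, span_m=0.249)
    freq = rng.uniform(0.05, 0.95, size=(200, 4))
    n = np.full_like(freq, 20, dtype=np.int64)
    table = genodata.AlleleFrequencyTable(["Out", "A", "B", "C"], freq, n, snps)
    blocks = fstats.make_blocks(snps)
    return table, blocks


@pytest.fixture(scope="session")
def small_scenario():
    """Three-source scenario at desk scale: 5,000 sites, sampled panel."""
    n_snps = 5000
    graph = simulate.three_source_graph(n_snps=n_snps)
    snps = simulate.uniform_snp_map(n_snps, graph.chrom_lengths_m, seed=0)
    freqs = simulate.simulate_frequencies(graph, seed=11)
    return graph, snps, freqs
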