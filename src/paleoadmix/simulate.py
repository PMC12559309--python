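"""Synthetic data with the statistical structure ancient-DNA admixture
inference assumes.

Three layers, each independently seeded and fully deterministic:

* **Allele frequencies on an admixture graph** — ancestral frequencies are
  drawn uniformly, each branch applies Balding-Nichols drift
  (p_child ~ Beta(p(1-F)/F, (1-p)(1-F)/F)), and admixed populations mix
  their sources' frequencies linearly. This frequency-level model (rather
  than a full coalescent) has analytic expectations for f-statistics and is
  fast enough for replicated experiments.
* **Ancestry tracts** — a two-state Markov jump process along each
  chromosome with switch rates q_{A->B} = (1-alpha)*t and
  q_{B->A} = alpha*t per Morgan, so the stationary ancestry fraction is
  alpha and ancestry autocovariance decays as exp(-t*d): the decay rate
  read off by the dating module equals the generations since admixture.
* **Reads** — per-site Poisson coverage, one true allele per read, and
  terminal C->T / G->A deamination with probability delta*exp(-position/5),
  feeding pseudo-haploid calling, coverage thinning and damage profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genodata import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    IndividualRecord,
    PileupTable,
    SnpRecord,
)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class AdmixtureEvent:
    """A pulse admixture: ``target`` is formed as a mixture of ``sources``
    with proportions ``alphas`` (summing to 1), ``t_generations`` before
    sampling."""

    target: str
    sources: tuple[str, ...]
    alphas: tuple[float, ...]
    t_generations: float

    def __post_init__(self) -> None:
        if len(self.sources) != len(self.alphas):
            raise ValueError("sources and alphas differ in length")
        if abs(sum(self.alphas) - 1.0) > 1e-9:
            raise ValueError("admixture proportions must sum to 1")
        if self.t_generations < 0:
            raise ValueError("admixture time must be >= 0")


@dataclass
class AdmixtureGraphSpec:
    """Simulation truth: a population tree with per-branch drift F and pulse
    admixture events, over a uniform genetic map.

    ``branches`` maps population -> (parent or None for the root, F); F must
    lie in (0, 1). Admixed populations appear only in ``admixtures``.
    """

    branches: dict[str, tuple[str | None, float]]
    admixtures: list[AdmixtureEvent] = field(default_factory=list)
    outgroup: str = ""
    chrom_lengths_m: tuple[float, ...] = tuple([1.0] * 22)
    n_snps: int = 50_000

    def __post_init__(self) -> None:
        for pop, (parent, f_drift) in self.branches.items():
            if not (0.0 < f_drift < 1.0):
                raise ValueError(f"branch {pop}: F must be in (0,1)")
            if parent is not None and parent not in self.branches:
                raise ValueError(f"branch {pop}: unknown parent {parent}")
        names = set(self.branches) | {e.target for e in self.admixtures}
        if self.outgroup and self.outgroup not in names:
            raise ValueError(f"outgroup {self.outgroup} not in graph")

    @property
    def populations(self) -> list[str]:
        return list(self.branches) + [e.target for e in self.admixtures]


@dataclass
class SimulatedDataset:
    """A panel plus ground truth, regenerable bit-identically from the
    recorded seed."""

    matrix: GenotypeMatrix
    true_freqs: dict[str, np.ndarray]
    truth: dict
    pileups: PileupTable | None = None


# ---------------------------------------------------------------------------
# Maps and frequencies
# ---------------------------------------------------------------------------


def uniform_snp_map(
    n_snps: int, chrom_lengths_m: Sequence[float], seed: int = 0
) -> list[SnpRecord]:
    """Evenly spaced sites on a uniform 1 cM/Mb map, allocated to
    chromosomes proportionally to genetic length; ref/alt pairs drawn
    uniformly over the 12 ordered base pairs."""
    rng = np.random.default_rng(seed)
    lengths = np.asarray(chrom_lengths_m, dtype=float)
    per_chrom = np.maximum(
        np.round(n_snps * lengths / lengths.sum()).astype(int), 1
    )
    per_chrom[-1] += n_snps - per_chrom.sum()
    snps: list[SnpRecord] = []
    for ci, (length, m) in enumerate(zip(lengths, per_chrom), start=1):
        gpos = (np.arange(m) + 0.5) / m * length
        ppos = np.round(gpos * 1e8).astype(int) + 1  # 1 cM/Mb
        pair_idx = rng.integers(0, 4, size=(m, 2))
        for i in range(m):
            a, b = pair_idx[i]
            if a == b:
                b = (b + 1) % 4
            snps.append(
                SnpRecord(
                    f"rs{ci}_{i}",
                    str(ci),
                    float(gpos[i]),
                    int(ppos[i]),
                    _BASES[a],
                    _BASES[b],
                )
            )
    return snps


def _drift(p: np.ndarray, f_drift: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step; fixed frequencies stay fixed."""
    scale = (1.0 - f_drift) / f_drift
    interior = (p > 0) & (p < 1)
    out = p.copy()
    if interior.any():
        a = np.maximum(p[interior] * scale, 1e-12)
        b = np.maximum((1.0 - p[interior]) * scale, 1e-12)
        out[interior] = rng.beta(a, b)
    return out


def simulate_frequencies(
    graph: AdmixtureGraphSpec, seed: int
) -> dict[str, np.ndarray]:
    """Per-population per-site ALT frequencies under the graph.

    Ancestral frequencies are Uniform(0.05, 0.95) per site; every branch
    applies Balding-Nichols drift; admixed populations are the linear
    mixture of their sources' frequencies.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_snps
    p_root = rng.uniform(0.05, 0.95, size=n)
    freqs: dict[str, np.ndarray] = {}
    pending = dict(graph.branches)
    # resolve tree nodes in dependency order
    while pending:
        progressed = False
        for pop, (parent, f_drift) in list(pending.items()):
            if parent is None:
                freqs[pop] = _drift(p_root, f_drift, rng)
            elif parent in freqs:
                freqs[pop] = _drift(freqs[parent], f_drift, rng)
            else:
                continue
            del pending[pop]
            progressed = True
        if not progressed:
            raise ValueError("admixture graph has unresolvable (cyclic) branches")
    for event in graph.admixtures:
        missing = [s for s in event.sources if s not in freqs]
        if missing:
            raise ValueError(f"admixture sources not in graph: {missing}")
        mix = np.zeros(n)
        for alpha, src in zip(event.alphas, event.sources):
            mix += alpha * freqs[src]
        freqs[event.target] = mix
    return freqs


def frequency_table(
    freq_by_pop: Mapping[str, np.ndarray],
    snps: Sequence[SnpRecord],
    n_alleles: int = 1000,
) -> AlleleFrequencyTable:
    """Wrap true population frequencies as an :class:`AlleleFrequencyTable`
    (an effectively infinite reference panel; ``n_alleles`` is nominal)."""
    pops = list(freq_by_pop)
    freq = np.column_stack([np.asarray(freq_by_pop[p], dtype=float) for p in pops])
    n = np.full(freq.shape, n_alleles, dtype=np.int64)
    return AlleleFrequencyTable(pops, freq, n, list(snps))


# ---------------------------------------------------------------------------
# Ancestry tracts
# ---------------------------------------------------------------------------


def simulate_tracts(
    alpha: float,
    t_generations: float,
    chrom_lengths_m: Sequence[float],
    seed: int,
) -> list[list[tuple[float, float, int]]]:
    """Two-ancestry tract structure per chromosome.

    Ancestry 0 (stationary fraction ``alpha``) and ancestry 1 alternate
    along each chromosome under a Markov jump process with switch rates
    q_{0->1} = (1-alpha)*t and q_{1->0} = alpha*t per Morgan; ancestry
    autocovariance then decays as exp(-t*d). Returns, per chromosome, a
    list of (start_M, end_M, ancestry) segments.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if t_generations < 1:
        raise ValueError("admixture time must be >= 1 generation")
    rng = np.random.default_rng(seed)
    rates = ((1.0 - alpha) * t_generations, alpha * t_generations)
    chromosomes: list[list[tuple[float, float, int]]] = []
    for length in chrom_lengths_m:
        state = 0 if rng.random() < alpha else 1
        pos = 0.0
        segments: list[tuple[float, float, int]] = []
        while pos < length:
            rate = rates[state]
            jump = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            end = min(pos + jump, length)
            segments.append((pos, end, state))
            pos = end
            state = 1 - state
        chromosomes.append(segments)
    return chromosomes


def ancestry_labels(
    tracts: list[list[tuple[float, float, int]]],
    snps: Sequence[SnpRecord],
    populations: tuple[str, str],
) -> np.ndarray:
    """Map tract segments to a per-site array of source-population labels."""
    chrom_order = list(dict.fromkeys(s.chrom for s in snps))
    if len(chrom_order) != len(tracts):
        raise ValueError(
            f"{len(tracts)} tract chromosomes but {len(chrom_order)} in the map"
        )
    labels = np.empty(len(snps), dtype=object)
    per_chrom = {c: i for i, c in enumerate(chrom_order)}
    for i, s in enumerate(snps):
        segments = tracts[per_chrom[s.chrom]]
        for start, end, state in segments:
            if start <= s.genetic_pos <= end:
                labels[i] = populations[state]
                break
        else:  # genetic position beyond simulated length
            labels[i] = populations[segments[-1][2]]
    return labels


def compose_three_way_labels(
    alphas: tuple[float, float, float],
    populations: tuple[str, str, str],
    t_generations: float,
    snps: Sequence[SnpRecord],
    chrom_lengths_m: Sequence[float],
    seed: int,
) -> np.ndarray:
    """Three-way local ancestry as two stacked two-way tract processes: the
    third source versus the pooled first two, then the first versus the
    second within the pooled tracts."""
    a1, a2, a3 = alphas
    if abs(a1 + a2 + a3 - 1.0) > 1e-9:
        raise ValueError("alphas must sum to 1")
    outer = simulate_tracts(a3, t_generations, chrom_lengths_m, seed)
    inner = simulate_tracts(
        a1 / (a1 + a2), t_generations, chrom_lengths_m, seed + 1
    )
    lab_outer = ancestry_labels(outer, snps, (populations[2], "_rest"))
    lab_inner = ancestry_labels(inner, snps, (populations[0], populations[1]))
    return np.where(lab_outer == populations[2], lab_outer, lab_inner)


# ---------------------------------------------------------------------------
# Individuals and reads
# ---------------------------------------------------------------------------


def simulate_individual(
    freq_by_pop: Mapping[str, np.ndarray],
    ancestry: str | np.ndarray | Sequence[np.ndarray],
    ploidy: int,
    seed: int,
) -> np.ndarray:
    """Genotype calls for one individual.

    ``ancestry`` is a population label (unadmixed), a per-site label array
    shared by all haplotypes, or one label array per haplotype (diploid
    individuals draw two tract sets independently). Each allele is
    Bernoulli(p of the local ancestry's source population); a haploid
    individual's single allele is doubled (pseudo-haploid convention).
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    some = next(iter(freq_by_pop.values()))
    n = len(some)
    if isinstance(ancestry, str):
        hap_labels = [np.full(n, ancestry, dtype=object)] * ploidy
    elif isinstance(ancestry, np.ndarray):
        hap_labels = [ancestry] * ploidy
    else:
        hap_labels = list(ancestry)
        if len(hap_labels) != ploidy:
            raise ValueError("need one ancestry label array per haplotype")
    rng = np.random.default_rng(seed)
    alleles = np.zeros(n, dtype=np.int8)
    for labels in hap_labels:
        p = np.empty(n)
        for pop in np.unique(labels.astype(str)):
            sel = labels == pop
            p[sel] = np.asarray(freq_by_pop[pop])[sel]
        alleles += (rng.random(n) < p).astype(np.int8)
    if ploidy == 1:
        alleles *= 2
    return alleles


def simulate_reads(
    genotypes: np.ndarray,
    snps: Sequence[SnpRecord],
    mean_cov: float,
    damage_delta: float = 0.0,
    read_len: int = 60,
    seed: int = 0,
) -> PileupTable:
    """Read pileups over known genotypes.

    Coverage is Poisson(``mean_cov``) per site; each read samples one of the
    individual's two allele copies; post-mortem deamination converts a read
    C to T (and G to A at the 3' end) with probability
    ``damage_delta * exp(-(position-1)/5)`` at the read position covering
    the site, drawn uniformly along the read.
    """
    if mean_cov <= 0:
        raise ValueError("mean coverage must be > 0")
    if not 0.0 <= damage_delta <= 0.5:
        raise ValueError("damage_delta must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    n = len(snps)
    cov = rng.poisson(mean_cov, size=n)
    site_idx = np.repeat(np.arange(n), cov)
    n_reads = len(site_idx)
    g = np.asarray(genotypes, dtype=float)[site_idx]
    is_alt = rng.random(n_reads) < g / 2.0
    ref_bases = np.array([_BASES.index(s.ref_allele) for s in snps])[site_idx]
    alt_bases = np.array([_BASES.index(s.alt_allele) for s in snps])[site_idx]
    bases = np.where(is_alt, alt_bases, ref_bases)
    if damage_delta > 0:
        pos5 = rng.integers(1, read_len + 1, size=n_reads)
        pos3 = read_len - pos5 + 1
        p_ct = damage_delta * np.exp(-(pos5 - 1) / 5.0)
        p_ga = damage_delta * np.exp(-(pos3 - 1) / 5.0)
        u = rng.random(n_reads)
        is_c = bases == _BASES.index("C")
        is_g = bases == _BASES.index("G")
        bases = np.where(is_c & (u < p_ct), _BASES.index("T"), bases)
        bases = np.where(is_g & (u < p_ga), _BASES.index("A"), bases)
    counts = np.bincount(site_idx * 4 + bases, minlength=n * 4).reshape(n, 4)
    return PileupTable(list(snps), counts)


def simulate_damaged_reads(
    n_reads: int,
    read_len: int,
    damage_delta: float,
    seed: int,
) -> list[tuple[str, str]]:
    """(read, reference) pairs with terminal deamination for damage-profile
    estimation: reference bases uniform over A/C/G/T; C->T flips at the 5'
    end and G->A flips at the 3' end with probability
    ``damage_delta * exp(-(position-1)/5)``."""
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    for _ in range(n_reads):
        ref_idx = rng.integers(0, 4, size=read_len)
        read_idx = ref_idx.copy()
        pos5 = np.arange(read_len)
        p_ct = damage_delta * np.exp(-pos5 / 5.0)
        p_ga = damage_delta * np.exp(-(read_len - 1 - pos5) / 5.0)
        u = rng.random(read_len)
        ct = (ref_idx == 1) & (u < p_ct)
        ga = (ref_idx == 2) & (u < p_ga)
        read_idx[ct] = 3
        read_idx[ga] = 0
        out.append(
            (
                "".join(_BASES[i] for i in read_idx),
                "".join(_BASES[i] for i in ref_idx),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Study-shaped scenario
# ---------------------------------------------------------------------------

#: Source and right population names of the canonical three-source scenario.
SOURCES = ("Jomon_like", "Kamchatka_like", "Amur_like")
RIGHTS = ("R1", "R2", "R3", "R4", "R5", "R6")
OUTGROUP = "Outgroup"


def three_source_graph(
    n_snps: int = 50_000,
    n_chrom: int = 22,
    chrom_length_m: float = 1.0,
) -> AdmixtureGraphSpec:
    """Admixture-graph truth emulating the study system: an outgroup, three
    drifted source lineages (Jomon-, Kamchatka- and Amur-like), and six
    right populations differentially related to the sources."""
    branches: dict[str, tuple[str | None, float]] = {
        OUTGROUP: (None, 0.30),
        "anc1": (None, 0.05),
        "R1": ("anc1", 0.10),
        "R5": ("anc1", 0.12),
        "R6": ("anc1", 0.15),
        "anc2": ("anc1", 0.05),
        "Jomon_like": ("anc2", 0.10),
        "R2": ("anc2", 0.08),
        "anc3": ("anc2", 0.05),
        "Kamchatka_like": ("anc3", 0.10),
        "R3": ("anc3", 0.08),
        "anc4": ("anc2", 0.05),
        "Amur_like": ("anc4", 0.10),
        "R4": ("anc4", 0.08),
    }
    return AdmixtureGraphSpec(
        branches=branches,
        outgroup=OUTGROUP,
        chrom_lengths_m=tuple([chrom_length_m] * n_chrom),
        n_snps=n_snps,
    )


def simulate_target_calls(
    graph: AdmixtureGraphSpec,
    freqs: dict[str, np.ndarray],
    snps: Sequence[SnpRecord],
    alphas: Sequence[float],
    sources: Sequence[str],
    t_generations: float,
    seed: int,
    mean_cov: float | None = 1.0,
    damage_delta: float = 0.0,
) -> tuple[np.ndarray, PileupTable | None]:
    """Simulate one admixed target genome: tract-structured diploid truth,
    optionally sequenced to ``mean_cov`` Poisson coverage and pseudo-haploid
    called downstream. Returns (diploid truth calls, pileups or None)."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(2**31 - 1, size=4)
    if len(sources) == 2:
        haps = []
        for h in range(2):
            tracts = simulate_tracts(
                alphas[0], t_generations, graph.chrom_lengths_m, int(sub_seeds[h])
            )
            haps.append(ancestry_labels(tracts, snps, (sources[0], sources[1])))
    elif len(sources) == 3:
        haps = [
            compose_three_way_labels(
                tuple(alphas), tuple(sources), t_generations, snps,
                graph.chrom_lengths_m, int(sub_seeds[h]) % (2**30),
            )
            for h in range(2)
        ]
    else:
        raise ValueError("2 or 3 sources supported")
    truth = simulate_individual(freqs, haps, ploidy=2, seed=int(sub_seeds[2]))
    pileups = None
    if mean_cov is not None:
        pileups = simulate_reads(
            truth, snps, mean_cov, damage_delta, seed=int(sub_seeds[3])
        )
    return truth, pileups


def simulate_panel(
    graph: AdmixtureGraphSpec,
    freqs: dict[str, np.ndarray],
    snps: Sequence[SnpRecord],
    n_per_pop: int = 10,
    seed: int = 0,
    populations: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Sample diploid reference individuals for every (or the given)
    population of the graph."""
    rng = np.random.default_rng(seed)
    pops = list(populations) if populations is not None else [
        p for p in graph.populations if not p.startswith("anc")
    ]
    inds: list[IndividualRecord] = []
    cols: list[np.ndarray] = []
    for pop in pops:
        for i in range(n_per_pop):
            cols.append(
                simulate_individual(
                    freqs, pop, ploidy=2, seed=int(rng.integers(2**31 - 1))
                )
            )
            inds.append(IndividualRecord(f"{pop}_{i}", pop))
    return GenotypeMatrix(list(snps), inds, np.column_stack(cols))
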