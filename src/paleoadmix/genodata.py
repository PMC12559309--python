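"""Genotype panels for ancient-DNA population genetics.

Data model and I/O for pseudo-haploid / diploid genotype panels in the
EIGENSTRAT format family, plus the read-level operations that precede every
downstream statistic: random-read pseudo-haploid calling, transversion
filtering, binomial coverage thinning, panel intersection and per-population
allele frequencies.

Conventions
-----------
* Physical positions are 1-based; genetic positions are Morgans internally.
* Genotype calls count ALT alleles: 0, 1, 2; missing is ``MISSING`` (-1) in
  memory and ``9`` on disk. Pseudo-haploid individuals carry only {0, 2,
  MISSING}.
* All stochastic operations take an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
_DISK_MISSING = 9

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs produced by a transition read on either strand
_TRANSITION_PAIRS = frozenset({frozenset({"C", "T"}), frozenset({"G", "A"})})
_AMBIGUOUS_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic site: id, chromosome, genetic position (Morgans),
    1-based physical position, ref and alt alleles."""

    snp_id: str
    chrom: str
    genetic_pos: float
    physical_pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        for a in (self.ref_allele, self.alt_allele):
            if a not in _BASES:
                raise ValueError(f"{self.snp_id}: allele {a!r} not in A/C/G/T")
        if self.physical_pos < 1:
            raise ValueError(f"{self.snp_id}: physical position must be >= 1")
        if self.genetic_pos < 0:
            raise ValueError(f"{self.snp_id}: genetic position must be >= 0")


@dataclass(frozen=True)
class IndividualRecord:
    """Panel member: id, population label, sex (M/F/U), pseudo-haploid flag."""

    ind_id: str
    population: str
    sex: str = "U"
    pseudo_haploid: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "U"):
            raise ValueError(f"{self.ind_id}: sex must be M, F or U")


class GenotypeMatrix:
    """Sites x individuals matrix of ALT-allele counts.

    Parameters
    ----------
    snps
        Ordered sequence of :class:`SnpRecord`.
    individuals
        Ordered sequence of :class:`IndividualRecord`; ids must be unique.
    calls
        ``(n_sites, n_individuals)`` integer array with values in
        {0, 1, 2, MISSING}. Pseudo-haploid columns may only hold {0, 2,
        MISSING}.
    """

    def __init__(
        self,
        snps: Sequence[SnpRecord],
        individuals: Sequence[IndividualRecord],
        calls: np.ndarray,
    ) -> None:
        self.snps = list(snps)
        self.individuals = list(individuals)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.snps), len(self.individuals)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.snps)} sites x {len(self.individuals)} individuals"
            )
        ids = [ind.ind_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in panel")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")
        for j, ind in enumerate(self.individuals):
            if ind.pseudo_haploid and np.any(calls[:, j] == 1):
                raise ValueError(
                    f"pseudo-haploid individual {ind.ind_id} carries a het call"
                )
        self.calls = calls

    # -- conveniences -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chrom": [s.chrom for s in self.snps],
                "genetic_pos": [s.genetic_pos for s in self.snps],
                "physical_pos": [s.physical_pos for s in self.snps],
                "ref": [s.ref_allele for s in self.snps],
                "alt": [s.alt_allele for s in self.snps],
            }
        )

    def ind_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ind_id": [i.ind_id for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "population": [i.population for i in self.individuals],
                "pseudo_haploid": [i.pseudo_haploid for i in self.individuals],
            }
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.snps[i] for i in index], self.individuals, self.calls[index]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"<GenotypeMatrix {self.n_sites} sites x {self.n_individuals} "
            f"individuals, {len(self.populations)} populations>"
        )


@dataclass(frozen=True)
class PileupSite:
    """Post-filter read counts at one site."""

    snp: SnpRecord
    base_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for base, count in self.base_counts.items():
            if base not in _BASES:
                raise ValueError(f"pileup base {base!r} not in A/C/G/T")
            if count < 0:
                raise ValueError("negative read count")


class PileupTable:
    """Vectorised pileup container: ``counts[site, base]`` for bases A,C,G,T
    at the sites of an associated SNP list."""

    def __init__(self, snps: Sequence[SnpRecord], counts: np.ndarray) -> None:
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(snps), 4):
            raise ValueError("counts must be (n_sites, 4) for bases A,C,G,T")
        if (counts < 0).any():
            raise ValueError("negative read count")
        self.snps = list(snps)
        self.counts = counts

    @property
    def n_sites(self) -> int:
        return len(self.snps)

    def mean_coverage(self) -> float:
        return float(self.counts.sum() / max(self.n_sites, 1))

    def site(self, i: int) -> PileupSite:
        return PileupSite(
            self.snps[i], dict(zip(_BASES, (int(c) for c in self.counts[i])))
        )


@dataclass
class AlleleFrequencyTable:
    """Per-population ALT-allele frequencies.

    ``freq[site, pop]`` is NaN exactly where ``n[site, pop]`` (observed allele
    count) is 0.
    """

    populations: list[str]
    freq: np.ndarray  # (n_sites, n_pops) float, NaN where missing
    n: np.ndarray  # (n_sites, n_pops) int allele counts
    snps: list[SnpRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.freq.shape != self.n.shape:
            raise ValueError("freq and n shapes differ")
        if self.freq.shape[1] != len(self.populations):
            raise ValueError("population count mismatch")
        with np.errstate(invalid="ignore"):
            if np.any((self.freq < -1e-12) | (self.freq > 1 + 1e-12)):
                raise ValueError("frequencies outside [0, 1]")
        miss = self.n == 0
        if np.any(~np.isnan(self.freq[miss])) or np.any(np.isnan(self.freq[~miss])):
            raise ValueError("freq must be NaN exactly where n == 0")

    def take_sites(self, index: np.ndarray) -> "AlleleFrequencyTable":
        index = np.asarray(index)
        return AlleleFrequencyTable(
            list(self.populations),
            self.freq[index],
            self.n[index],
            [self.snps[i] for i in index] if self.snps else [],
        )

    def column(self, population: str) -> np.ndarray:
        try:
            j = self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None
        return self.freq[:, j]

    def columns(self, populations: Iterable[str]) -> np.ndarray:
        return np.column_stack([self.column(p) for p in populations])


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------


def _read_snp_file(snp_path: str | Path) -> list[SnpRecord]:
    snps: list[SnpRecord] = []
    with open(snp_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise ValueError(
                    f"{snp_path}:{lineno}: expected 6 columns, got {len(parts)}"
                )
            sid, chrom, gpos, ppos, ref, alt = parts
            if ref not in _BASES or alt not in _BASES or ref == alt:
                raise ValueError(
                    f"{snp_path}:{lineno}: malformed allele columns {ref!r}/{alt!r}"
                )
            snps.append(
                SnpRecord(sid, chrom, float(gpos), int(ppos), ref, alt)
            )
    return snps


def _read_ind_file(ind_path: str | Path) -> list[IndividualRecord]:
    inds: list[IndividualRecord] = []
    with open(ind_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ValueError(
                    f"{ind_path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            iid, sex, pop = parts
            inds.append(IndividualRecord(iid, pop, sex if sex in "MFU" else "U"))
    return inds


def read_eigenstrat(
    geno_path: str | Path,
    snp_path: str | Path,
    ind_path: str | Path,
    pseudo_haploid: Iterable[str] = (),
) -> GenotypeMatrix:
    """Read an EIGENSTRAT geno/snp/ind triplet (ASCII or packed geno).

    The geno dialect is auto-detected: packed files start with a ``GENO``
    header record. ``9`` (ASCII) / ``3`` (packed) decode to MISSING.
    The format carries no pseudo-haploid flag; pass the ids of
    random-read-called individuals in ``pseudo_haploid``.
    """
    snps = _read_snp_file(snp_path)
    inds = _read_ind_file(ind_path)
    ph = set(pseudo_haploid)
    if ph:
        unknown = ph - {i.ind_id for i in inds}
        if unknown:
            raise ValueError(f"pseudo_haploid ids not in ind file: {sorted(unknown)}")
        inds = [
            replace(i, pseudo_haploid=True) if i.ind_id in ph else i for i in inds
        ]
    with open(geno_path, "rb") as fh:
        magic = fh.read(4)
    if magic == b"GENO":
        calls = _read_packed_geno(geno_path, len(snps), len(inds))
    else:
        calls = _read_ascii_geno(geno_path, len(snps), len(inds))
    return GenotypeMatrix(snps, inds, calls)


def _read_ascii_geno(path: str | Path, n_snps: int, n_inds: int) -> np.ndarray:
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_inds:
                raise ValueError(
                    f"{path}:{lineno}: geno line has {len(line)} genotypes "
                    f"but ind file lists {n_inds} individuals"
                )
            row = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
            if not np.isin(row, (0, 1, 2, _DISK_MISSING)).all():
                raise ValueError(f"{path}:{lineno}: invalid genotype character")
            rows.append(row.astype(np.int8))
    if len(rows) != n_snps:
        raise ValueError(
            f"{path}: {len(rows)} geno lines but snp file lists {n_snps} sites"
        )
    calls = np.array(rows, dtype=np.int8).reshape(len(rows), n_inds)
    calls[calls == _DISK_MISSING] = MISSING
    return calls


def _read_packed_geno(path: str | Path, n_snps: int, n_inds: int) -> np.ndarray:
    record_len = max(48, (n_inds + 3) // 4)
    raw = Path(path).read_bytes()
    header = raw[:record_len].split(b"\x00", 1)[0].decode("ascii", "replace").split()
    if len(header) < 3 or header[0] != "GENO":
        raise ValueError(f"{path}: malformed packed geno header")
    h_ind, h_snp = int(header[1]), int(header[2])
    if (h_ind, h_snp) != (n_inds, n_snps):
        raise ValueError(
            f"{path}: packed header declares {h_ind} individuals x {h_snp} sites "
            f"but snp/ind files list {n_inds} x {n_snps}"
        )
    body = raw[record_len:]
    if len(body) != n_snps * record_len:
        raise ValueError(
            f"{path}: packed body has {len(body)} bytes, "
            f"expected {n_snps * record_len}"
        )
    rows = np.frombuffer(body, dtype=np.uint8).reshape(n_snps, record_len)
    # 2-bit fields, most significant pair first
    bits = np.unpackbits(rows, axis=1)
    two_bit = (bits[:, 0::2] << 1) | bits[:, 1::2]
    calls = two_bit[:, :n_inds].astype(np.int8)
    calls[calls == 3] = MISSING
    return calls


def write_eigenstrat(
    matrix: GenotypeMatrix, prefix: str | Path, packed: bool = False
) -> tuple[Path, Path, Path]:
    """Write geno/snp/ind files at ``prefix``; ASCII geno by default."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno_path = prefix.with_suffix(".geno")
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")

    with open(snp_path, "w") as fh:
        for s in matrix.snps:
            # shortest round-trip float keeps read(write(x)) lossless
            fh.write(
                f"{s.snp_id}\t{s.chrom}\t{s.genetic_pos!r}\t"
                f"{s.physical_pos}\t{s.ref_allele}\t{s.alt_allele}\n"
            )
    with open(ind_path, "w") as fh:
        for i in matrix.individuals:
            fh.write(f"{i.ind_id}\t{i.sex}\t{i.population}\n")

    disk = matrix.calls.copy()
    disk[disk == MISSING] = _DISK_MISSING
    if not packed:
        with open(geno_path, "w") as fh:
            for row in disk:
                fh.write("".join(chr(ord("0") + int(v)) for v in row) + "\n")
    else:
        n_inds = matrix.n_individuals
        record_len = max(48, (n_inds + 3) // 4)
        header = f"GENO {n_inds} {matrix.n_sites} 0 0".encode("ascii")
        with open(geno_path, "wb") as fh:
            fh.write(header.ljust(record_len, b"\x00"))
            packed_vals = disk.astype(np.uint8)
            packed_vals[packed_vals == _DISK_MISSING] = 3
            for row in packed_vals:
                padded = np.zeros(record_len * 4, dtype=np.uint8)
                padded[:n_inds] = row
                bits = np.zeros(record_len * 8, dtype=np.uint8)
                bits[0::2] = padded >> 1
                bits[1::2] = padded & 1
                fh.write(np.packbits(bits).tobytes())
    return geno_path, snp_path, ind_path


def read_pileup_tsv(path: str | Path, snps: Sequence[SnpRecord]) -> PileupTable:
    """Read a pileup TSV (chrom, pos, countA, countC, countG, countT) aligned
    to ``snps`` by (chrom, physical position); absent sites get zero counts."""
    table = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "A", "C", "G", "T"],
        dtype={"chrom": str},
    )
    lookup = {
        (row.chrom, int(row.pos)): (row.A, row.C, row.G, row.T)
        for row in table.itertuples()
    }
    counts = np.zeros((len(snps), 4), dtype=np.int64)
    for i, s in enumerate(snps):
        counts[i] = lookup.get((s.chrom, s.physical_pos), (0, 0, 0, 0))
    return PileupTable(snps, counts)


def write_pileup_tsv(pileups: PileupTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s, row in zip(pileups.snps, pileups.counts):
            fh.write(
                f"{s.chrom}\t{s.physical_pos}\t{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\n"
            )
    return path


def read_vcf(path: str | Path, pseudo_haploid: bool = False) -> GenotypeMatrix:
    """Convenience import of a plain-text biallelic-SNV VCF (GT field only).

    Genetic positions are filled at 1 cM/Mb; sites that are not biallelic
    SNVs are skipped.
    """
    snps: list[SnpRecord] = []
    rows: list[list[int]] = []
    sample_ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            if ref not in _BASES or alt not in _BASES or ref == alt:
                continue
            row = []
            for entry in parts[9:]:
                gt = entry.split(":")[0].replace("|", "/")
                alleles = [a for a in gt.split("/") if a != "."]
                if not alleles:
                    row.append(MISSING)
                else:
                    row.append(sum(int(a) for a in alleles) * (2 // len(alleles)))
            snps.append(
                SnpRecord(
                    vid if vid != "." else f"{chrom}_{pos}",
                    chrom,
                    pos * 1e-8,
                    pos,
                    ref,
                    alt,
                )
            )
            rows.append(row)
    inds = [
        IndividualRecord(sid, "VCF", pseudo_haploid=pseudo_haploid)
        for sid in sample_ids
    ]
    return GenotypeMatrix(snps, inds, np.array(rows, dtype=np.int8).reshape(len(snps), len(inds)))


# ---------------------------------------------------------------------------
# Calling, filtering, thinning
# ---------------------------------------------------------------------------


def pseudo_haploid_call(pileup: PileupSite, rng_seed: int) -> int:
    """Random-read pseudo-haploid call: draw one read uniformly among reads
    matching ref or alt and double its allele (ref -> 0, alt -> 2); MISSING
    when no read matches either allele."""
    n_ref = int(pileup.base_counts.get(pileup.snp.ref_allele, 0))
    n_alt = int(pileup.base_counts.get(pileup.snp.alt_allele, 0))
    total = n_ref + n_alt
    if total == 0:
        return MISSING
    rng = np.random.default_rng(rng_seed)
    return 2 if rng.integers(total) < n_alt else 0


def pseudo_haploid_call_all(pileups: PileupTable, rng_seed: int) -> np.ndarray:
    """Vectorised random-read calls for every site of a pileup table."""
    rng = np.random.default_rng(rng_seed)
    ref_idx = np.array([_BASES.index(s.ref_allele) for s in pileups.snps])
    alt_idx = np.array([_BASES.index(s.alt_allele) for s in pileups.snps])
    rows = np.arange(pileups.n_sites)
    n_ref = pileups.counts[rows, ref_idx]
    n_alt = pileups.counts[rows, alt_idx]
    total = n_ref + n_alt
    calls = np.full(pileups.n_sites, MISSING, dtype=np.int8)
    covered = total > 0
    draw = rng.random(pileups.n_sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(covered, n_alt / np.maximum(total, 1), 0.0)
    calls[covered] = np.where(draw[covered] < p_alt[covered], 2, 0)
    return calls


def filter_transversions(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Drop transition sites (C/T or G/A allele pairs, either strand reading),
    preserving the order of the remaining sites."""
    keep = [
        i
        for i, s in enumerate(matrix.snps)
        if frozenset({s.ref_allele, s.alt_allele}) not in _TRANSITION_PAIRS
    ]
    return matrix.take_sites(np.array(keep, dtype=int))


def is_transversion(snp: SnpRecord) -> bool:
    return frozenset({snp.ref_allele, snp.alt_allele}) not in _TRANSITION_PAIRS


def downsample_pileups(
    pileups: PileupTable,
    current_mean_cov: float,
    target_mean_cov: float,
    rng_seed: int,
) -> PileupTable:
    """Binomially thin every base count with retention probability
    ``target_mean_cov / current_mean_cov``."""
    if target_mean_cov > current_mean_cov:
        raise ValueError(
            f"target coverage {target_mean_cov} exceeds current {current_mean_cov}"
        )
    p = target_mean_cov / current_mean_cov if current_mean_cov > 0 else 0.0
    rng = np.random.default_rng(rng_seed)
    thinned = rng.binomial(pileups.counts, p)
    return PileupTable(pileups.snps, thinned)


def intersect_panels(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two panels on the intersection of (chrom, physical_pos) sites,
    concatenating individuals.

    Allele reconciliation: strand-ambiguous sites (A/T, C/G) are dropped;
    matching pairs are kept as-is; swapped pairs recode the second panel's
    calls 0<->2; strand-complement (and complement+swap) pairs are
    reconciled likewise; any other mismatch is dropped.
    """
    ids_a = {i.ind_id for i in a.individuals}
    dup = ids_a & {i.ind_id for i in b.individuals}
    if dup:
        raise ValueError(f"duplicate individual ids across panels: {sorted(dup)}")

    index_b = {(s.chrom, s.physical_pos): j for j, s in enumerate(b.snps)}
    keep_a: list[int] = []
    keep_b: list[int] = []
    flip_b: list[bool] = []
    for i, sa in enumerate(a.snps):
        j = index_b.get((sa.chrom, sa.physical_pos))
        if j is None:
            continue
        sb = b.snps[j]
        pair_a = frozenset({sa.ref_allele, sa.alt_allele})
        pair_b = frozenset({sb.ref_allele, sb.alt_allele})
        if pair_a in _AMBIGUOUS_PAIRS or pair_b in _AMBIGUOUS_PAIRS:
            continue
        if (sb.ref_allele, sb.alt_allele) == (sa.ref_allele, sa.alt_allele):
            flip = False
        elif (sb.ref_allele, sb.alt_allele) == (sa.alt_allele, sa.ref_allele):
            flip = True
        else:
            comp = (_COMPLEMENT[sb.ref_allele], _COMPLEMENT[sb.alt_allele])
            if comp == (sa.ref_allele, sa.alt_allele):
                flip = False
            elif comp == (sa.alt_allele, sa.ref_allele):
                flip = True
            else:
                continue
        keep_a.append(i)
        keep_b.append(j)
        flip_b.append(flip)

    calls_b = b.calls[np.array(keep_b, dtype=int)] if keep_b else np.empty(
        (0, b.n_individuals), dtype=np.int8
    )
    if keep_b:
        flip_arr = np.array(flip_b)
        flipped = calls_b[flip_arr]
        nonmiss = flipped != MISSING
        flipped[nonmiss] = 2 - flipped[nonmiss]
        calls_b[flip_arr] = flipped
    calls_a = a.calls[np.array(keep_a, dtype=int)] if keep_a else np.empty(
        (0, a.n_individuals), dtype=np.int8
    )
    merged_snps = [a.snps[i] for i in keep_a]
    merged = np.concatenate([calls_a, calls_b], axis=1)
    return GenotypeMatrix(merged_snps, a.individuals + b.individuals, merged)


def allele_frequencies(
    matrix: GenotypeMatrix,
    population_grouping: Mapping[str, Sequence[str]] | None = None,
) -> AlleleFrequencyTable:
    """Per-population ALT-allele frequencies.

    Diploid individuals contribute 2 observed alleles per non-missing call;
    pseudo-haploid individuals contribute 1 (their call / 2). ``n`` records
    the observed allele count; frequency is NaN where ``n`` is 0.

    ``population_grouping`` optionally maps population labels to individual
    ids; by default, groups come from the panel's population labels.
    """
    id_to_col = {ind.ind_id: j for j, ind in enumerate(matrix.individuals)}
    if population_grouping is None:
        grouping: dict[str, list[int]] = {}
        for j, ind in enumerate(matrix.individuals):
            grouping.setdefault(ind.population, []).append(j)
    else:
        grouping = {}
        for pop, ids in population_grouping.items():
            cols = []
            for iid in ids:
                if iid not in id_to_col:
                    raise KeyError(f"unknown individual id {iid!r} for population {pop!r}")
                cols.append(id_to_col[iid])
            if not cols:
                raise ValueError(f"population {pop!r} has no individuals")
            grouping[pop] = cols

    pops = list(grouping)
    n_sites = matrix.n_sites
    freq = np.full((n_sites, len(pops)), np.nan)
    counts = np.zeros((n_sites, len(pops)), dtype=np.int64)
    ph = np.array([ind.pseudo_haploid for ind in matrix.individuals])
    calls = matrix.calls
    for k, pop in enumerate(pops):
        cols = np.array(grouping[pop], dtype=int)
        sub = calls[:, cols]
        sub_ph = ph[cols]
        obs = sub != MISSING
        # alleles observed: 1 for pseudo-haploid, 2 for diploid
        alleles = obs * np.where(sub_ph, 1, 2)[None, :]
        # alt alleles: call/2 for pseudo-haploid, call for diploid
        alt = np.where(obs, sub, 0).astype(float)
        alt = np.where(sub_ph[None, :], alt / 2.0, alt)
        n_k = alleles.sum(axis=1)
        counts[:, k] = n_k
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, k] = np.where(n_k > 0, alt.sum(axis=1) / np.maximum(n_k, 1), np.nan)
    return AlleleFrequencyTable(pops, freq, counts, list(matrix.snps))
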