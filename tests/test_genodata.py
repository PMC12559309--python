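"""Genotype data model, EIGENSTRAT I/O, calling, filtering, thinning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleoadmix import genodata
from paleoadmix.genodata import (
    MISSING,
    GenotypeMatrix,
    IndividualRecord,
    PileupSite,
    PileupTable,
    SnpRecord,
    allele_frequencies,
    downsample_pileups,
    filter_transversions,
    intersect_panels,
    pseudo_haploid_call,
    pseudo_haploid_call_all,
    read_eigenstrat,
    write_eigenstrat,
)
from conftest import make_snps, random_matrix


class TestEigenstratIO:
    def test_ascii_round_trip_small(self, tmp_path):
        snps = make_snps(3)
        inds = [IndividualRecord("a", "P1"), IndividualRecord("b", "P2")]
        calls = np.array([[0, 2], [1, MISSING], [2, 0]], dtype=np.int8)
        m = GenotypeMatrix(snps, inds, calls)
        write_eigenstrat(m, tmp_path / "toy")
        back = read_eigenstrat(
            tmp_path / "toy.geno", tmp_path / "toy.snp", tmp_path / "toy.ind"
        )
        assert back == m

    def test_geno_line_029_decodes_with_missing(self, tmp_path):
        snps = make_snps(1)
        inds = [IndividualRecord(c, "P") for c in "abc"]
        (tmp_path / "t.geno").write_text("029\n")
        (tmp_path / "t.snp").write_text(
            "s0\t1\t0.0\t100\tA\tC\n"
        )
        (tmp_path / "t.ind").write_text("a\tU\tP\nb\tU\tP\nc\tU\tP\n")
        m = read_eigenstrat(tmp_path / "t.geno", tmp_path / "t.snp", tmp_path / "t.ind")
        assert m.calls[0].tolist() == [0, 2, MISSING]

    def test_ascii_write_read_write_byte_identical(self, tmp_path):
        m = random_matrix(100, 10, seed=3, missing_rate=0.1)
        write_eigenstrat(m, tmp_path / "a")
        back = read_eigenstrat(
            tmp_path / "a.geno", tmp_path / "a.snp", tmp_path / "a.ind"
        )
        write_eigenstrat(back, tmp_path / "b")
        for ext in (".geno", ".snp", ".ind"):
            assert (tmp_path / f"a{ext}").read_bytes() == (
                tmp_path / f"b{ext}"
            ).read_bytes()

    def test_packed_round_trip(self, tmp_path):
        m = random_matrix(57, 13, seed=5, missing_rate=0.2)
        ph = [i.ind_id for i in m.individuals if i.pseudo_haploid]
        write_eigenstrat(m, tmp_path / "p", packed=True)
        back = read_eigenstrat(
            tmp_path / "p.geno", tmp_path / "p.snp", tmp_path / "p.ind",
            pseudo_haploid=ph,
        )
        assert back == m

    def test_empty_matrix_writes_empty_bodies(self, tmp_path):
        m = GenotypeMatrix([], [], np.empty((0, 0), dtype=np.int8))
        write_eigenstrat(m, tmp_path / "e")
        assert (tmp_path / "e.geno").read_text() == ""
        assert (tmp_path / "e.snp").read_text() == ""

    def test_single_site_single_geno_line(self, tmp_path):
        m = random_matrix(1, 4, seed=6)
        write_eigenstrat(m, tmp_path / "one")
        assert len((tmp_path / "one.geno").read_text().splitlines()) == 1

    def test_dimension_mismatch_names_counts(self, tmp_path):
        m = random_matrix(5, 3, seed=7)
        write_eigenstrat(m, tmp_path / "x")
        # drop one snp line -> count mismatch
        lines = (tmp_path / "x.snp").read_text().splitlines()[:-1]
        (tmp_path / "x.snp").write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="5 geno lines|4"):
            read_eigenstrat(tmp_path / "x.geno", tmp_path / "x.snp", tmp_path / "x.ind")

    def test_malformed_allele_column_reports_line(self, tmp_path):
        (tmp_path / "bad.snp").write_text("s0\t1\t0.0\t100\tA\tA\n")
        (tmp_path / "bad.geno").write_text("0\n")
        (tmp_path / "bad.ind").write_text("a\tU\tP\n")
        with pytest.raises(ValueError, match=":1"):
            read_eigenstrat(
                tmp_path / "bad.geno", tmp_path / "bad.snp", tmp_path / "bad.ind"
            )

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), miss=st.floats(0.0, 0.3))
    def test_round_trip_identity_random_fixtures(self, seed, miss, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        m = random_matrix(30, 7, seed=seed, missing_rate=miss)
        ph = [i.ind_id for i in m.individuals if i.pseudo_haploid]
        for packed in (False, True):
            write_eigenstrat(m, tmp / f"r{packed}", packed=packed)
            back = read_eigenstrat(
                tmp / f"r{packed}.geno", tmp / f"r{packed}.snp",
                tmp / f"r{packed}.ind", pseudo_haploid=ph,
            )
            assert back == m


class TestVcfImport:
    def test_biallelic_gt_import(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\trs1\tA\tC\t.\t.\t.\tGT\t0/1\t1/1\n"
            "1\t200\trs2\tG\tT\t.\t.\t.\tGT\t0|0\t./.\n"
            "1\t300\trs3\tG\tGA\t.\t.\t.\tGT\t0/0\t0/0\n"
        )
        (tmp_path / "v.vcf").write_text(vcf)
        m = genodata.read_vcf(tmp_path / "v.vcf")
        assert m.n_sites == 2  # indel skipped
        assert m.calls[0].tolist() == [1, 2]
        assert m.calls[1].tolist() == [0, MISSING]


class TestPseudoHaploidCall:
    def _site(self, n_ref, n_alt, other=0):
        snp = SnpRecord("s", "1", 0.0, 100, "A", "C")
        return PileupSite(snp, {"A": n_ref, "C": n_alt, "G": other})

    def test_single_allele_always_that_allele(self):
        assert all(
            pseudo_haploid_call(self._site(5, 0), seed) == 0 for seed in range(50)
        )

    def test_no_matching_reads_missing(self):
        assert pseudo_haploid_call(self._site(0, 0, other=3), 0) == MISSING

    def test_balanced_counts_hit_half(self):
        calls = np.array(
            [pseudo_haploid_call(self._site(1, 1), seed) for seed in range(10_000)]
        )
        frac_alt = (calls == 2).mean()
        assert abs(frac_alt - 0.5) < 0.015

    def test_marginal_matches_base_proportions_chi2(self):
        from scipy.stats import chisquare

        calls = np.array(
            [pseudo_haploid_call(self._site(3, 1), seed) for seed in range(10_000)]
        )
        observed = [(calls == 0).sum(), (calls == 2).sum()]
        _, p = chisquare(observed, [7500, 2500])
        assert p > 0.001

    def test_vectorised_caller_matches_proportions(self):
        snps = make_snps(5000)
        counts = np.tile([2, 2, 0, 0], (5000, 1))
        calls = pseudo_haploid_call_all(PileupTable(snps, counts), 11)
        assert abs((calls == 2).mean() - 0.5) < 0.03


class TestFilterTransversions:
    def test_keeps_only_transversion_pairs(self):
        pairs = [("A", "C"), ("C", "T"), ("G", "A"), ("A", "T")]
        snps = [
            SnpRecord(f"s{i}", "1", 0.001 * i, 100 + i, r, a)
            for i, (r, a) in enumerate(pairs)
        ]
        inds = [IndividualRecord("x", "P")]
        m = GenotypeMatrix(snps, inds, np.zeros((4, 1), dtype=np.int8))
        kept = filter_transversions(m)
        assert [(s.ref_allele, s.alt_allele) for s in kept.snps] == [
            ("A", "C"),
            ("A", "T"),
        ]

    def test_all_transversion_panel_identity(self):
        snps = make_snps(10, alleles=("A", "C"))
        m = GenotypeMatrix(
            snps, [IndividualRecord("x", "P")], np.ones((10, 1), dtype=np.int8)
        )
        assert filter_transversions(m) == m

    def test_kept_set_matches_brute_force_and_idempotent(self):
        m = random_matrix(1000, 3, seed=9)
        kept = filter_transversions(m)
        expect = {
            s.snp_id
            for s in m.snps
            if {s.ref_allele, s.alt_allele} not in ({"C", "T"}, {"G", "A"})
        }
        assert {s.snp_id for s in kept.snps} == expect
        assert filter_transversions(kept) == kept


class TestDownsampling:
    def test_target_equals_current_is_identity(self):
        snps = make_snps(20)
        p = PileupTable(snps, np.full((20, 4), 3))
        out = downsample_pileups(p, 12.0, 12.0, 0)
        assert np.array_equal(out.counts, p.counts)

    def test_target_zero_empties_counts(self):
        snps = make_snps(20)
        p = PileupTable(snps, np.full((20, 4), 3))
        assert downsample_pileups(p, 12.0, 0.0, 0).counts.sum() == 0

    def test_target_above_current_rejected(self):
        p = PileupTable(make_snps(5), np.ones((5, 4), dtype=int))
        with pytest.raises(ValueError, match="exceeds"):
            downsample_pileups(p, 1.0, 2.0, 0)

    def test_realised_coverage_concentrates_at_target(self):
        rng = np.random.default_rng(1)
        snps = make_snps(10_000)
        counts = np.zeros((10_000, 4), dtype=int)
        counts[:, 0] = rng.poisson(4.0, size=10_000)
        p = PileupTable(snps, counts)
        thinned = downsample_pileups(p, p.mean_coverage(), 1.0, 2)
        assert abs(thinned.mean_coverage() - 1.0) < 0.03

    def test_thinning_preserves_base_proportions(self):
        snps = make_snps(2000)
        counts = np.tile([6, 2, 0, 0], (2000, 1))
        p = PileupTable(snps, counts)
        thinned = downsample_pileups(p, 8.0, 2.0, 3)
        tot = thinned.counts.sum(axis=0)
        assert abs(tot[0] / (tot[0] + tot[1]) - 0.75) < 0.02


class TestIntersectPanels:
    def test_disjoint_sites_empty_merge(self):
        a = random_matrix(10, 2, seed=1)
        b = random_matrix(10, 2, seed=2)
        bsnps = [
            SnpRecord(s.snp_id, "9", s.genetic_pos, s.physical_pos, s.ref_allele, s.alt_allele)
            for s in b.snps
        ]
        b2 = GenotypeMatrix(
            bsnps,
            [IndividualRecord(f"q{j}", "Q") for j in range(2)],
            b.calls,
        )
        merged = intersect_panels(a, b2)
        assert merged.n_sites == 0
        assert merged.n_individuals == 4

    def test_identical_panels_double_individuals(self):
        a = random_matrix(50, 3, seed=4)
        b = GenotypeMatrix(
            a.snps,
            [IndividualRecord(f"q{j}", "Q", pseudo_haploid=a.individuals[j].pseudo_haploid)
             for j in range(3)],
            a.calls,
        )
        merged = intersect_panels(a, b)
        # strand-ambiguous sites are dropped by design; others survive
        ambiguous = sum(
            1 for s in a.snps if {s.ref_allele, s.alt_allele} in ({"A", "T"}, {"C", "G"})
        )
        assert merged.n_sites == a.n_sites - ambiguous
        assert merged.n_individuals == 6

    def test_allele_swapped_copy_recodes_to_original(self):
        snps = make_snps(30, alleles=("A", "C"))
        inds = [IndividualRecord("a", "P")]
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(30, 1)).astype(np.int8)
        a = GenotypeMatrix(snps, inds, calls)
        swapped_snps = [
            SnpRecord(s.snp_id, s.chrom, s.genetic_pos, s.physical_pos,
                      s.alt_allele, s.ref_allele)
            for s in snps
        ]
        b = GenotypeMatrix(
            swapped_snps, [IndividualRecord("b", "Q")], (2 - calls).astype(np.int8)
        )
        merged = intersect_panels(a, b)
        assert merged.n_sites == 30
        assert np.array_equal(merged.calls[:, 0], merged.calls[:, 1])

    def test_duplicate_individual_ids_rejected(self):
        a = random_matrix(5, 2, seed=1)
        with pytest.raises(ValueError, match="duplicate"):
            intersect_panels(a, a)


class TestAlleleFrequencies:
    def test_single_diploid_het(self):
        snps = make_snps(1)
        m = GenotypeMatrix(
            snps, [IndividualRecord("a", "P")], np.array([[1]], dtype=np.int8)
        )
        t = allele_frequencies(m)
        assert t.freq[0, 0] == 0.5
        assert t.n[0, 0] == 2

    def test_single_pseudo_haploid_alt(self):
        snps = make_snps(1)
        m = GenotypeMatrix(
            snps,
            [IndividualRecord("a", "P", pseudo_haploid=True)],
            np.array([[2]], dtype=np.int8),
        )
        t = allele_frequencies(m)
        assert t.freq[0, 0] == 1.0
        assert t.n[0, 0] == 1

    def test_mixed_panel_matches_hand_count(self):
        # diploid het (1 of 2), diploid hom-alt (2 of 2), pseudo-haploid ref (0 of 1)
        snps = make_snps(1)
        inds = [
            IndividualRecord("d1", "P"),
            IndividualRecord("d2", "P"),
            IndividualRecord("h1", "P", pseudo_haploid=True),
        ]
        m = GenotypeMatrix(snps, inds, np.array([[1, 2, 0]], dtype=np.int8))
        t = allele_frequencies(m)
        assert t.n[0, 0] == 5
        assert t.freq[0, 0] == pytest.approx(3 / 5)

    def test_missing_only_site_has_nan(self):
        snps = make_snps(1)
        m = GenotypeMatrix(
            snps, [IndividualRecord("a", "P")],
            np.array([[MISSING]], dtype=np.int8),
        )
        t = allele_frequencies(m)
        assert np.isnan(t.freq[0, 0]) and t.n[0, 0] == 0

    def test_unknown_individual_in_grouping_rejected(self, toy_matrix):
        with pytest.raises(KeyError, match="nope"):
            allele_frequencies(toy_matrix, {"G": ["nope"]})
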