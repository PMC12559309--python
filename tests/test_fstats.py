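"""f3/D statistics, block partitioning and the weighted block jackknife.

The reference implementations in this file (`brute_f3`, `brute_d`) are
deliberately plain per-site loops, independent of the package's vectorised
paths.
"""

import numpy as np
import pytest

from paleoadmix import fstats, genodata
from paleoadmix.fstats import (
    d_stat,
    f3_outgroup,
    make_blocks,
    outgroup_f3_scan,
    pairwise_f3_regression,
    rank_concordance,
)
from conftest import make_snps


# ---------------------------------------------------------------------------
# Independent brute-force oracle for ratio statistics with weighted jackknife
# ---------------------------------------------------------------------------


def brute_ratio_jackknife(num, den, block_of_site):
    """Delete-one-block weighted jackknife for sum(num)/sum(den), written as
    explicit loops."""
    blocks = sorted(set(block_of_site))
    theta = sum(num) / sum(den)
    loo, weights = [], []
    for b in blocks:
        keep = [i for i in range(len(num)) if block_of_site[i] != b]
        loo.append(sum(num[i] for i in keep) / sum(den[i] for i in keep))
        weights.append(sum(1 for i in range(len(num)) if block_of_site[i] == b))
    g = len(blocks)
    n = sum(weights)
    tau = [n / w * theta - (n / w - 1) * lv for w, lv in zip(weights, loo)]
    theta_j = g * theta - sum((1 - w / n) * lv for w, lv in zip(weights, loo))
    var = sum(
        (tv - theta_j) ** 2 / (n / w - 1) for tv, w in zip(tau, weights)
    ) / g
    return theta, var**0.5


def brute_f3(freq, out_i, a_i, b_i, block_of_site):
    num = [
        (freq[s][out_i] - freq[s][a_i]) * (freq[s][out_i] - freq[s][b_i])
        for s in range(len(freq))
    ]
    den = [1.0] * len(freq)
    return brute_ratio_jackknife(num, den, block_of_site)


def brute_d(freq, w_i, x_i, y_i, z_i, block_of_site):
    num, den = [], []
    for s in range(len(freq)):
        w, x, y, z = (freq[s][i] for i in (w_i, x_i, y_i, z_i))
        num.append((w - x) * (y - z))
        den.append((w + x - 2 * w * x) * (y + z - 2 * y * z))
    return brute_ratio_jackknife(num, den, block_of_site)


class TestMakeBlocks:
    def test_single_short_chromosome_one_block(self):
        snps = make_snps(10, span_m=0.04)
        assert make_blocks(snps).n_blocks == 1

    def test_uniform_span_splits_by_ceiling(self):
        snps = make_snps(13, span_m=0.12)  # 0, 0.01, ..., 0.12
        assert make_blocks(snps).n_blocks == 3

    def test_random_maps_cover_all_sites_within_span(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            snps = []
            for chrom in ("1", "2", "3"):
                gpos = np.sort(rng.uniform(0, 0.8, size=60))
                snps.extend(
                    genodata.SnpRecord(f"c{chrom}s{i}", chrom, float(g),
                                       i + 1, "A", "C")
                    for i, g in enumerate(gpos)
                )
            part = make_blocks(snps)
            assert part.site_count.sum() == len(snps)
            gp = np.array([s.genetic_pos for s in snps])
            for b in range(part.n_blocks):
                sel = part.block_index == b
                assert gp[sel].max() - gp[sel].min() <= 0.05 + 1e-12
                chroms = {snps[i].chrom for i in np.flatnonzero(sel)}
                assert len(chroms) == 1

    def test_unsorted_input_rejected(self):
        snps = make_snps(5)[::-1]
        with pytest.raises(ValueError, match="sorted"):
            make_blocks(snps)


class TestF3:
    def test_zero_when_both_match_outgroup(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        t2 = genodata.AlleleFrequencyTable(
            table.populations,
            np.column_stack([table.freq[:, 0]] * 4),
            table.n,
            table.snps,
        )
        res = f3_outgroup(t2, "Out", "A", "B", blocks)
        assert res.estimate == pytest.approx(0.0, abs=1e-15)

    def test_maximal_divergence_gives_one(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        freq = np.column_stack(
            [np.zeros(200), np.ones(200), np.ones(200), np.ones(200)]
        )
        t2 = genodata.AlleleFrequencyTable(table.populations, freq, table.n, table.snps)
        res = f3_outgroup(t2, "Out", "A", "B", blocks)
        assert res.estimate == pytest.approx(1.0)

    def test_symmetry_in_pair(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        ab = f3_outgroup(table, "Out", "A", "B", blocks)
        ba = f3_outgroup(table, "Out", "B", "A", blocks)
        assert ab.estimate == ba.estimate
        assert ab.jackknife.se == ba.jackknife.se

    def test_matches_brute_force_jackknife(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        res = f3_outgroup(table, "Out", "A", "B", blocks)
        est, se = brute_f3(
            table.freq.tolist(), 0, 1, 2, blocks.block_index.tolist()
        )
        assert res.estimate == pytest.approx(est, abs=1e-12)
        assert res.jackknife.se == pytest.approx(se, abs=1e-12)

    def test_jackknife_matches_classical_se_for_iid_sites(self):
        # equal-sized blocks, iid sites: need many blocks so the jackknife's
        # own estimation noise (~sqrt(2/g)) is below the 5% tolerance
        rng = np.random.default_rng(12)
        n_per, n_chrom = 200, 50
        snps = [
            genodata.SnpRecord(f"c{c}s{i}", str(c + 1),
                               0.999 * i / (n_per - 1), i + 1, "A", "C")
            for c in range(n_chrom)
            for i in range(n_per)
        ]
        n = len(snps)
        freq = rng.uniform(0.05, 0.95, size=(n, 3))
        table = genodata.AlleleFrequencyTable(
            ["Out", "A", "B"], freq, np.full((n, 3), 10, dtype=np.int64), snps
        )
        blocks = make_blocks(snps)
        res = f3_outgroup(table, "Out", "A", "B", blocks)
        num = (freq[:, 0] - freq[:, 1]) * (freq[:, 0] - freq[:, 2])
        classical = num.std(ddof=1) / np.sqrt(n)
        assert res.jackknife.se == pytest.approx(classical, rel=0.05)


class TestDStat:
    def test_equal_yz_frequencies_zero(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        freq = table.freq.copy()
        freq[:, 3] = freq[:, 2]
        t2 = genodata.AlleleFrequencyTable(table.populations, freq, table.n, table.snps)
        res = d_stat(t2, "Out", "A", "B", "C", blocks)
        assert res.estimate == pytest.approx(0.0, abs=1e-15)

    def test_swapping_last_pair_flips_sign(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        r1 = d_stat(table, "Out", "A", "B", "C", blocks)
        r2 = d_stat(table, "Out", "A", "C", "B", blocks)
        assert r1.estimate == pytest.approx(-r2.estimate, abs=1e-15)
        assert r1.jackknife.se == pytest.approx(r2.jackknife.se, abs=1e-15)

    def test_swapping_first_pair_flips_sign(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        r1 = d_stat(table, "Out", "A", "B", "C", blocks)
        r2 = d_stat(table, "A", "Out", "B", "C", blocks)
        assert r1.estimate == pytest.approx(-r2.estimate, abs=1e-15)

    def test_double_swap_invariance(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        r1 = d_stat(table, "Out", "A", "B", "C", blocks)
        r2 = d_stat(table, "A", "Out", "C", "B", blocks)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-15)

    def test_matches_brute_force_jackknife(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        res = d_stat(table, "Out", "A", "B", "C", blocks)
        est, se = brute_d(
            table.freq.tolist(), 0, 1, 2, 3, blocks.block_index.tolist()
        )
        assert res.estimate == pytest.approx(est, abs=1e-12)
        assert res.jackknife.se == pytest.approx(se, abs=1e-12)

    def test_attraction_of_x_to_fourth_population_positive(self):
        rng = np.random.default_rng(77)
        n = 500
        snps = make_snps(n, span_m=0.249)
        p0 = rng.uniform(0.2, 0.8, size=n)
        shared = np.clip(p0 + rng.normal(0, 0.15, n), 0.01, 0.99)
        freq = np.column_stack(
            [
                p0,  # W outgroup
                np.clip(shared + rng.normal(0, 0.05, n), 0.01, 0.99),  # X
                np.clip(p0 + rng.normal(0, 0.05, n), 0.01, 0.99),  # Y
                np.clip(shared + rng.normal(0, 0.05, n), 0.01, 0.99),  # Z
            ]
        )
        table = genodata.AlleleFrequencyTable(
            ["W", "X", "Y", "Z"], freq, np.full((n, 4), 20, dtype=np.int64), snps
        )
        blocks = make_blocks(snps)
        res = d_stat(table, "W", "X", "Y", "Z", blocks)
        assert res.estimate > 0
        assert res.jackknife.z > 3

    def test_all_fixed_sites_rejected(self):
        n = 20
        snps = make_snps(n, span_m=0.249)
        freq = np.ones((n, 4))
        table = genodata.AlleleFrequencyTable(
            ["W", "X", "Y", "Z"], freq, np.full((n, 4), 4, dtype=np.int64), snps
        )
        with pytest.raises(ValueError, match="denominator"):
            d_stat(table, "W", "X", "Y", "Z", make_blocks(snps))


class TestScan:
    def test_identical_population_ranks_first(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        freq = np.column_stack(
            [table.freq[:, 0], table.freq[:, 1], table.freq[:, 1], table.freq[:, 0]]
        )
        t2 = genodata.AlleleFrequencyTable(
            ["Out", "T", "Twin", "OutLike"], freq, table.n, table.snps
        )
        scan = outgroup_f3_scan(t2, "T", ["Twin", "OutLike"], "Out", blocks)
        assert scan.iloc[0]["population"] == "Twin"

    def test_single_candidate_single_row(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        scan = outgroup_f3_scan(table, "A", ["B"], "Out", blocks)
        assert len(scan) == 1

    def test_rank_order_follows_drift_proximity(self, small_scenario):
        graph, snps, freqs = small_scenario
        table = __import__("paleoadmix").simulate.frequency_table(
            {k: v for k, v in freqs.items() if not k.startswith("anc")}, snps
        )
        blocks = make_blocks(snps)
        scan = outgroup_f3_scan(
            table, "Jomon_like", ["R2", "R5", "R6", "Outgroup"], "Outgroup", blocks
        )
        # R2 shares the most drift with the Jomon-like lineage; outgroup least
        # (scanning the outgroup against itself yields f3 = 0 by definition)
        assert scan.iloc[0]["population"] == "R2"
        assert scan.iloc[-1]["population"] == "Outgroup"

    def test_failed_candidate_reported_with_reason(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        scan = outgroup_f3_scan(table, "A", ["B", "Nonexistent"], "Out", blocks)
        bad = scan[scan["population"] == "Nonexistent"].iloc[0]
        assert bad["reason"] != ""
        assert np.isnan(bad["f3"])


class TestPairwiseRegression:
    def test_identical_targets_give_identity_line(self):
        rng = np.random.default_rng(3)
        n = 400
        snps = make_snps(n, span_m=0.249)
        freq = rng.uniform(0.05, 0.95, size=(n, 6))
        table = genodata.AlleleFrequencyTable(
            ["Out", "T", "C1", "C2", "C3", "C4"], freq,
            np.full((n, 6), 20, dtype=np.int64), snps,
        )
        blocks = make_blocks(snps)
        reg = pairwise_f3_regression(
            table, "Out", "T", "T", ["C1", "C2", "C3", "C4"], blocks
        )
        assert reg.slope == pytest.approx(1.0, abs=1e-9)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(reg.table["residual"], 0.0, atol=1e-12)

    def test_residuals_sum_to_zero(self, small_scenario):
        graph, snps, freqs = small_scenario
        from paleoadmix import simulate as sim

        table = sim.frequency_table(
            {k: v for k, v in freqs.items() if not k.startswith("anc")}, snps
        )
        blocks = make_blocks(snps)
        reg = pairwise_f3_regression(
            table, "Outgroup", "Jomon_like", "Kamchatka_like",
            ["R1", "R2", "R3", "R4", "R5", "R6"], blocks,
        )
        assert reg.table["residual"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_perturbed_candidate_has_largest_positive_residual(self):
        rng = np.random.default_rng(9)
        n = 400
        snps = make_snps(n, span_m=0.249)
        base = rng.uniform(0.05, 0.95, size=n)
        # candidates drift from the same base; C2 gains extra affinity to TB only
        freq = {
            "Out": rng.uniform(0.05, 0.95, size=n),
            "TA": np.clip(base + rng.normal(0, 0.1, n), 0.01, 0.99),
            "TB": np.clip(base + rng.normal(0, 0.1, n), 0.01, 0.99),
        }
        for c in ("C1", "C2", "C3", "C4"):
            freq[c] = np.clip(base + rng.normal(0, 0.1, n), 0.01, 0.99)
        freq["C2"] = np.clip(0.6 * freq["C2"] + 0.4 * freq["TB"], 0.01, 0.99)
        pops = list(freq)
        table = genodata.AlleleFrequencyTable(
            pops, np.column_stack([freq[p] for p in pops]),
            np.full((n, len(pops)), 20, dtype=np.int64), snps,
        )
        blocks = make_blocks(snps)
        reg = pairwise_f3_regression(
            table, "Out", "TA", "TB", ["C1", "C2", "C3", "C4"], blocks
        )
        t = reg.table.set_index("population")
        assert t.loc["C2", "residual"] == t["residual"].max()

    def test_jackknife_residual_se_close_to_site_bootstrap(self):
        rng = np.random.default_rng(100)
        n_per, n_chrom = 160, 25
        snps = [
            genodata.SnpRecord(f"c{c}s{i}", str(c + 1),
                               0.999 * i / (n_per - 1), i + 1, "A", "C")
            for c in range(n_chrom)
            for i in range(n_per)
        ]
        n = len(snps)
        pops = ["Out", "TA", "TB", "C1", "C2", "C3", "C4", "C5"]
        freq = rng.uniform(0.05, 0.95, size=(n, len(pops)))
        table = genodata.AlleleFrequencyTable(
            pops, freq, np.full((n, len(pops)), 20, dtype=np.int64), snps
        )
        blocks = make_blocks(snps)
        cands = ["C1", "C2", "C3", "C4", "C5"]
        reg = pairwise_f3_regression(table, "Out", "TA", "TB", cands, blocks)

        def residuals(f):
            x = np.array(
                [np.mean((f[:, 0] - f[:, 1]) * (f[:, 0] - f[:, 3 + k]))
                 for k in range(5)]
            )
            y = np.array(
                [np.mean((f[:, 0] - f[:, 2]) * (f[:, 0] - f[:, 3 + k]))
                 for k in range(5)]
            )
            slope, intercept = np.polyfit(x, y, 1)
            return y - slope * x - intercept

        boot = np.array(
            [
                residuals(freq[rng.integers(0, n, size=n)])
                for _ in range(200)
            ]
        )
        boot_se = boot.std(axis=0, ddof=1)
        ratio = reg.table["residual_se"].to_numpy() / boot_se
        assert abs(ratio.mean() - 1.0) < 0.10

    def test_too_few_candidates_rejected(self, freq_fixture_200):
        table, blocks = freq_fixture_200
        with pytest.raises(ValueError, match="3 candidates"):
            pairwise_f3_regression(table, "Out", "A", "B", ["C", "A"][:2], blocks)


class TestRankConcordance:
    def test_identical_vectors(self):
        v = np.array([3.0, 1.0, 2.0, 5.0])
        assert rank_concordance(v, v) == pytest.approx(1.0)

    def test_reversed_vector(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert rank_concordance(v, v[::-1]) == pytest.approx(-1.0)

    def test_tie_handling_matches_hand_ranking(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        b = np.array([2.0, 1.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        # hand computation with average ranks: ra = [1, 2.5, 2.5, 4..10]
        ra = np.array([1, 2.5, 2.5, 4, 5, 6, 7, 8, 9, 10])
        rb = np.array([2, 1, 3, 4, 5, 6, 7, 8, 9, 10])
        expect = np.corrcoef(ra, rb)[0, 1]
        assert rank_concordance(a, b) == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(rank_concordance(np.ones(5), np.arange(5.0)))
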