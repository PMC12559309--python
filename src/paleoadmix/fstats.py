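"""f-statistics with weighted block jackknife.

Outgroup f3 and D (ABBA-BABA) statistics computed from per-population allele
frequencies, with standard errors from a weighted delete-one-block jackknife
over contiguous genomic blocks (Busing-style pseudovalue formula, block
weights = usable site counts). Also: outgroup-f3 affinity scans, the pairwise
outgroup-f3 regression with per-population deviation Z, and Spearman rank
concordance between site-filtered replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import AlleleFrequencyTable, SnpRecord

DEFAULT_BLOCK_SIZE_M = 0.05  # Morgans
SIGNIFICANCE_Z = 3.0


@dataclass
class BlockPartition:
    """Assignment of sites to contiguous jackknife blocks.

    Blocks never span chromosomes; ``block_index[site]`` maps every site to
    exactly one block.
    """

    block_index: np.ndarray  # (n_sites,) int
    n_blocks: int
    chrom: list[str]  # per block
    span: np.ndarray  # genetic span per block (Morgans)
    site_count: np.ndarray  # sites per block

    def __post_init__(self) -> None:
        self.block_index = np.asarray(self.block_index, dtype=np.int64)


@dataclass
class BlockJackknifeEstimate:
    """Point estimate with weighted delete-one-block jackknife SE and Z."""

    estimate: float
    se: float
    z: float
    n_blocks: int
    loo_values: np.ndarray = field(repr=False)  # leave-one-out estimates
    block_weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("jackknife needs at least 2 blocks")
        if self.se < 0:
            raise ValueError("SE must be non-negative")


@dataclass
class F3Result:
    outgroup: str
    pop_a: str
    pop_b: str
    jackknife: BlockJackknifeEstimate
    n_sites: int

    @property
    def estimate(self) -> float:
        return self.jackknife.estimate


@dataclass
class DResult:
    w: str
    x: str
    y: str
    z: str
    jackknife: BlockJackknifeEstimate
    n_sites: int

    @property
    def estimate(self) -> float:
        return self.jackknife.estimate


@dataclass
class PairwiseF3Regression:
    """OLS of one outgroup-f3 scan on another across shared candidate
    populations, with per-candidate deviation Z from a delete-one-block
    jackknife in which both f3 vectors and the regression are recomputed."""

    table: pd.DataFrame  # population, x, y, residual, residual_se, residual_z, significant
    slope: float
    intercept: float


def make_blocks(
    snps: list[SnpRecord], block_size_morgans: float = DEFAULT_BLOCK_SIZE_M
) -> BlockPartition:
    """Greedy left-to-right blocks of genetic span <= ``block_size_morgans``
    within each chromosome; block weight = site count.

    Sites must be sorted by (chromosome, genetic position).
    """
    n = len(snps)
    chroms = [s.chrom for s in snps]
    gpos = np.array([s.genetic_pos for s in snps])
    for i in range(1, n):
        if chroms[i] == chroms[i - 1] and gpos[i] < gpos[i - 1]:
            raise ValueError(
                f"sites not sorted by genetic position within chromosome "
                f"{chroms[i]} (index {i})"
            )
    block_index = np.zeros(n, dtype=np.int64)
    block_chrom: list[str] = []
    spans: list[float] = []
    counts: list[int] = []
    cur = -1
    start = 0.0
    last_chrom = None
    last_pos = 0.0
    for i in range(n):
        if chroms[i] != last_chrom or gpos[i] - start > block_size_morgans:
            if cur >= 0:
                spans.append(last_pos - start)
                counts.append(int(np.sum(block_index[:i] == cur)))
            cur += 1
            start = gpos[i]
            last_chrom = chroms[i]
            block_chrom.append(chroms[i])
        block_index[i] = cur
        last_pos = gpos[i]
    if cur >= 0:
        spans.append(last_pos - start)
        counts.append(int(np.sum(block_index == cur)))
    return BlockPartition(
        block_index,
        cur + 1,
        block_chrom,
        np.array(spans),
        np.array(counts, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Weighted jackknife core
# ---------------------------------------------------------------------------


def weighted_jackknife(
    theta_full: float, loo: np.ndarray, weights: np.ndarray
) -> BlockJackknifeEstimate:
    """Weighted delete-one-block jackknife SE for an estimator whose full-data
    value is ``theta_full`` and whose leave-one-out values are ``loo`` with
    block weights ``weights`` (e.g. site counts).

    Uses the pseudovalue formula for unequal block sizes: with n = sum of
    weights, h_j = n / m_j,

        tau_j   = h_j * theta - (h_j - 1) * theta_{-j}
        theta_J = g * theta - sum_j (1 - m_j/n) * theta_{-j}
        var     = (1/g) * sum_j (tau_j - theta_J)^2 / (h_j - 1)

    The reported point estimate is the full-data value.
    """
    loo = np.asarray(loo, dtype=float)
    weights = np.asarray(weights, dtype=float)
    g = len(loo)
    n = weights.sum()
    h = n / weights
    tau = h * theta_full - (h - 1.0) * loo
    theta_j = g * theta_full - float(((1.0 - weights / n) * loo).sum())
    var = float((((tau - theta_j) ** 2) / (h - 1.0)).sum() / g)
    se = float(np.sqrt(max(var, 0.0)))
    z = theta_full / se if se > 0 else np.inf * np.sign(theta_full) if theta_full else 0.0
    return BlockJackknifeEstimate(
        estimate=float(theta_full),
        se=se,
        z=float(z),
        n_blocks=g,
        loo_values=loo,
        block_weights=weights,
    )


def _ratio_block_jackknife(
    num: np.ndarray,
    den: np.ndarray,
    block_index: np.ndarray,
    n_blocks: int,
    usable: np.ndarray,
) -> BlockJackknifeEstimate:
    """Jackknife for a statistic of the form sum(num)/sum(den) over usable
    sites, deleting one block at a time. Block weights are usable site
    counts; blocks with no usable site are excluded."""
    bidx = block_index[usable]
    num_u = num[usable]
    den_u = den[usable]
    num_b = np.bincount(bidx, weights=num_u, minlength=n_blocks)
    den_b = np.bincount(bidx, weights=den_u, minlength=n_blocks)
    cnt_b = np.bincount(bidx, minlength=n_blocks)
    nonempty = cnt_b > 0
    if nonempty.sum() < 2:
        raise ValueError("fewer than 2 usable jackknife blocks")
    tot_num = num_b.sum()
    tot_den = den_b.sum()
    if tot_den == 0:
        raise ValueError("zero denominator: statistic undefined")
    loo_den = tot_den - den_b[nonempty]
    if np.any(loo_den == 0):
        raise ValueError("zero denominator in a leave-one-out block")
    theta = tot_num / tot_den
    loo = (tot_num - num_b[nonempty]) / loo_den
    return weighted_jackknife(theta, loo, cnt_b[nonempty].astype(float))


# ---------------------------------------------------------------------------
# f3 and D
# ---------------------------------------------------------------------------


def f3_outgroup(
    freqs: AlleleFrequencyTable,
    out: str,
    pop_a: str,
    pop_b: str,
    blocks: BlockPartition,
) -> F3Result:
    """Outgroup f3(out; A, B): mean over usable sites of
    (p_out - p_A)(p_out - p_B), SE/Z by weighted block jackknife.

    No outgroup-heterozygosity normalisation or inbreeding correction is
    applied (outgroup mode). Sites missing in any of the three populations
    are dropped for this statistic only.
    """
    p = freqs.columns([out, pop_a, pop_b])
    usable = ~np.isnan(p).any(axis=1)
    n_sites = int(usable.sum())
    if n_sites == 0:
        raise ValueError("no usable sites for f3")
    num = (p[:, 0] - p[:, 1]) * (p[:, 0] - p[:, 2])
    num = np.where(usable, num, 0.0)
    den = usable.astype(float)
    jk = _ratio_block_jackknife(num, den, blocks.block_index, blocks.n_blocks, usable)
    return F3Result(out, pop_a, pop_b, jk, n_sites)


def d_stat(
    freqs: AlleleFrequencyTable,
    w: str,
    x: str,
    y: str,
    z: str,
    blocks: BlockPartition,
) -> DResult:
    """D(W, X; Y, Z) = sum (w-x)(y-z) / sum (w+x-2wx)(y+z-2yz) over usable
    sites, jackknife SE/Z.

    Positive D means X shares excess drift with Z (the fourth population).
    """
    p = freqs.columns([w, x, y, z])
    usable = ~np.isnan(p).any(axis=1)
    if not usable.any():
        raise ValueError("no usable sites for D")
    pw, px, py, pz = p.T
    num = (pw - px) * (py - pz)
    den = (pw + px - 2 * pw * px) * (py + pz - 2 * py * pz)
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    jk = _ratio_block_jackknife(num, den, blocks.block_index, blocks.n_blocks, usable)
    return DResult(w, x, y, z, jk, int(usable.sum()))


def outgroup_f3_scan(
    freqs: AlleleFrequencyTable,
    target: str,
    candidate_list: list[str],
    out: str,
    blocks: BlockPartition,
) -> pd.DataFrame:
    """f3(out; target, X) for every candidate X, sorted descending by
    estimate (ties broken lexicographically). Candidates whose statistic is
    undefined appear as rows with NaN values and a ``reason``."""
    if not candidate_list:
        raise ValueError("candidate list is empty")
    rows = []
    for cand in candidate_list:
        try:
            res = f3_outgroup(freqs, out, target, cand, blocks)
            rows.append(
                {
                    "population": cand,
                    "f3": res.estimate,
                    "se": res.jackknife.se,
                    "z": res.jackknife.z,
                    "n_sites": res.n_sites,
                    "n_blocks": res.jackknife.n_blocks,
                    "reason": "",
                }
            )
        except (ValueError, KeyError) as exc:
            rows.append(
                {
                    "population": cand,
                    "f3": np.nan,
                    "se": np.nan,
                    "z": np.nan,
                    "n_sites": 0,
                    "n_blocks": 0,
                    "reason": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["f3", "population"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# Pairwise-f3 regression
# ---------------------------------------------------------------------------


def _f3_block_sums(
    freqs: AlleleFrequencyTable,
    out: str,
    target: str,
    candidates: list[str],
    blocks: BlockPartition,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block numerator sums and usable-site counts of f3(out; target, X)
    for each candidate X: arrays (n_blocks, n_candidates)."""
    g = blocks.n_blocks
    num_b = np.zeros((g, len(candidates)))
    cnt_b = np.zeros((g, len(candidates)))
    p_out = freqs.column(out)
    p_t = freqs.column(target)
    for k, cand in enumerate(candidates):
        p_c = freqs.column(cand)
        usable = ~(np.isnan(p_out) | np.isnan(p_t) | np.isnan(p_c))
        num = np.where(usable, (p_out - p_t) * (p_out - p_c), 0.0)
        num_b[:, k] = np.bincount(
            blocks.block_index, weights=num, minlength=g
        )
        cnt_b[:, k] = np.bincount(
            blocks.block_index, weights=usable.astype(float), minlength=g
        )
    return num_b, cnt_b


def _ols_residuals(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), y - (slope * x + intercept)


def pairwise_f3_regression(
    freqs: AlleleFrequencyTable,
    out: str,
    target_a: str,
    target_b: str,
    candidates: list[str],
    blocks: BlockPartition,
) -> PairwiseF3Regression:
    """Regression of f3(out; target_b, X) on f3(out; target_a, X) across
    candidate populations X, with per-candidate deviation Z.

    Residual SEs come from a delete-one-block jackknife in which both f3
    vectors and the OLS line are recomputed for every deleted block;
    |Z| >= 3 is flagged significant.
    """
    if len(candidates) < 3:
        raise ValueError("deviation regression needs at least 3 candidates")
    num_a, cnt_a = _f3_block_sums(freqs, out, target_a, candidates, blocks)
    num_b, cnt_b = _f3_block_sums(freqs, out, target_b, candidates, blocks)
    tot_cnt_a = cnt_a.sum(axis=0)
    tot_cnt_b = cnt_b.sum(axis=0)
    if np.any(tot_cnt_a == 0) or np.any(tot_cnt_b == 0):
        raise ValueError("a candidate has no usable sites")
    x_full = num_a.sum(axis=0) / tot_cnt_a
    y_full = num_b.sum(axis=0) / tot_cnt_b
    slope, intercept, resid_full = _ols_residuals(x_full, y_full)

    g = blocks.n_blocks
    resid_loo = np.zeros((g, len(candidates)))
    for j in range(g):
        ca = tot_cnt_a - cnt_a[j]
        cb = tot_cnt_b - cnt_b[j]
        if np.any(ca == 0) or np.any(cb == 0):
            resid_loo[j] = resid_full
            continue
        x_j = (num_a.sum(axis=0) - num_a[j]) / ca
        y_j = (num_b.sum(axis=0) - num_b[j]) / cb
        _, _, resid_loo[j] = _ols_residuals(x_j, y_j)
    # unweighted delete-one jackknife over blocks (near-equal block sizes)
    se = np.sqrt((g - 1) / g * ((resid_loo - resid_loo.mean(axis=0)) ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(se > 0, resid_full / se, 0.0)
    table = pd.DataFrame(
        {
            "population": candidates,
            "x": x_full,
            "y": y_full,
            "residual": resid_full,
            "residual_se": se,
            "residual_z": zval,
            "significant": np.abs(zval) >= SIGNIFICANCE_Z,
        }
    )
    return PairwiseF3Regression(table, slope, intercept)


def rank_concordance(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties); NaN for constant
    input vectors, where the coefficient is undefined."""
    vec_a = np.asarray(vec_a, dtype=float)
    vec_b = np.asarray(vec_b, dtype=float)
    if vec_a.shape != vec_b.shape or vec_a.ndim != 1 or len(vec_a) < 3:
        raise ValueError("need equal-length 1-d vectors with n >= 3")
    if np.all(vec_a == vec_a[0]) or np.all(vec_b == vec_b[0]):
        return float("nan")
    rho, _ = stats.spearmanr(vec_a, vec_b)
    return float(rho)


def results_table(results: list[F3Result | DResult]) -> pd.DataFrame:
    """Flat TSV-ready table of f3/D results."""
    rows = []
    for r in results:
        if isinstance(r, F3Result):
            rows.append(
                {
                    "statistic": "f3",
                    "pops": f"{r.outgroup};{r.pop_a},{r.pop_b}",
                    "estimate": r.estimate,
                    "se": r.jackknife.se,
                    "z": r.jackknife.z,
                    "n_sites": r.n_sites,
                    "n_blocks": r.jackknife.n_blocks,
                }
            )
        else:
            rows.append(
                {
                    "statistic": "D",
                    "pops": f"{r.w},{r.x};{r.y},{r.z}",
                    "estimate": r.estimate,
                    "se": r.jackknife.se,
                    "z": r.jackknife.z,
                    "n_sites": r.n_sites,
                    "n_blocks": r.jackknife.n_blocks,
                }
            )
    return pd.DataFrame(rows)
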