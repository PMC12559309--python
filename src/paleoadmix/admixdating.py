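"""Admixture-LD decay dating.

Estimates the time since a two-source admixture pulse from the decay of
weighted ancestry covariance with genetic distance. Each site is weighted by
the allele-frequency contrast of the assumed sources, w_s = p_A(s) - p_B(s);
the covariance of weighted genotype residuals between site pairs at genetic
distance d decays as A0 * exp(-lambda * d) + c, and the decay rate lambda
(per Morgan) estimates the number of generations since admixture. The affine
term c absorbs background LD and finite-panel bias. Standard errors come
from a delete-one-chromosome jackknife; a generation time converts
generations to calendar years BP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .fstats import weighted_jackknife
from .genodata import MISSING, AlleleFrequencyTable, SnpRecord

DEFAULT_BIN_SIZE_M = 0.001  # 0.1 cM
DEFAULT_MAX_DIST_M = 0.2  # 20 cM
DEFAULT_FIT_LO_M = 0.0045  # 0.45 cM


@dataclass
class AncestryCovarianceCurve:
    """Weighted ancestry covariance binned by genetic distance, with
    per-chromosome partial sums retained for the jackknife."""

    bin_centers: np.ndarray  # Morgans
    cov: np.ndarray  # bin means; NaN where no pairs
    n_pairs: np.ndarray
    chrom_labels: list[str]
    chrom_sums: np.ndarray = field(repr=False)  # (n_chrom, n_bins)
    chrom_pairs: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


@dataclass
class DateFit:
    """Exponential-decay fit: cov(d) = amplitude * exp(-rate * d) + affine.

    ``rate`` is in per-Morgan units and estimates generations since
    admixture (``t_generations``); its SE comes from delete-one-chromosome
    refits.
    """

    amplitude: float
    rate: float
    affine: float
    t_se: float
    fit_lo: float
    fit_hi: float
    n_chromosomes: int
    at_bound: bool = False

    @property
    def t_generations(self) -> float:
        return self.rate

    def to_dict(self) -> dict:
        return {
            "A0": self.amplitude,
            "t_generations": self.rate,
            "c": self.affine,
            "t_se": self.t_se,
            "fit_lo_M": self.fit_lo,
            "fit_hi_M": self.fit_hi,
            "n_chromosomes": self.n_chromosomes,
            "rate_at_zero_bound": self.at_bound,
        }


@dataclass
class CalendarDate:
    years_bp: float
    se_years: float
    generation_time: float
    sample_age_bp: float


def snp_weights(
    freqs: AlleleFrequencyTable, source_a: str, source_b: str
) -> np.ndarray:
    """Per-site weight w_s = p_A(s) - p_B(s); NaN where either source
    frequency is missing. Zero-contrast sites are retained (contribute 0)."""
    return freqs.column(source_a) - freqs.column(source_b)


def _residuals(
    target_calls: np.ndarray,
    weights: np.ndarray,
    p_mid: np.ndarray,
) -> np.ndarray:
    """r_s = w_s * (g_s/2 - pbar_s); NaN where call or weight missing."""
    calls = np.asarray(target_calls, dtype=float)
    obs = calls != MISSING
    r = np.where(obs, weights * (calls / 2.0 - p_mid), np.nan)
    return r


def ancestry_cov_curve(
    target_calls: np.ndarray,
    freqs: AlleleFrequencyTable,
    source_a: str,
    source_b: str,
    snps: list[SnpRecord] | None = None,
    bin_size: float = DEFAULT_BIN_SIZE_M,
    max_dist: float = DEFAULT_MAX_DIST_M,
    chunk: int = 1024,
) -> AncestryCovarianceCurve:
    """Weighted ancestry covariance of one target genome against genetic
    distance.

    For every intra-chromosome pair (s, s') with 0 < d <= ``max_dist``,
    accumulates r_s * r_s' (r_s = w_s*(g_s/2 - pbar_s), pbar the source
    midpoint frequency) into distance bins of width ``bin_size``; bin value
    is the mean over pairs. Missing calls and sites missing in either source
    are skipped pairwise. Per-chromosome partials are kept for the
    chromosome jackknife.
    """
    if snps is None:
        snps = freqs.snps
    w = snp_weights(freqs, source_a, source_b)
    p_mid = (freqs.column(source_a) + freqs.column(source_b)) / 2.0
    r = _residuals(target_calls, w, p_mid)
    gpos = np.array([s.genetic_pos for s in snps])
    chroms = np.array([s.chrom for s in snps])

    n_bins = int(np.ceil(max_dist / bin_size))
    chrom_labels = list(dict.fromkeys(chroms.tolist()))
    chrom_sums = np.zeros((len(chrom_labels), n_bins))
    chrom_pairs = np.zeros((len(chrom_labels), n_bins), dtype=np.int64)

    for ci, chrom in enumerate(chrom_labels):
        sel = (chroms == chrom) & ~np.isnan(r)
        g = gpos[sel]
        order = np.argsort(g, kind="stable")
        g = g[order]
        rc = r[sel][order]
        m = len(g)
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            d = g[None, :] - g[lo:hi, None]  # (chunk, m)
            ok = (d > 0) & (d <= max_dist)
            if not ok.any():
                continue
            bins = np.minimum((d[ok] / bin_size).astype(np.int64), n_bins - 1)
            prods = (rc[lo:hi, None] * rc[None, :])[ok]
            chrom_sums[ci] += np.bincount(bins, weights=prods, minlength=n_bins)
            chrom_pairs[ci] += np.bincount(bins, minlength=n_bins)

    total_pairs = chrom_pairs.sum(axis=0)
    if total_pairs.sum() == 0:
        raise ValueError("no site pairs fall inside the distance range")
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(
            total_pairs > 0, chrom_sums.sum(axis=0) / np.maximum(total_pairs, 1), np.nan
        )
    centers = (np.arange(n_bins) + 0.5) * bin_size
    return AncestryCovarianceCurve(
        centers, cov, total_pairs, chrom_labels, chrom_sums, chrom_pairs
    )


def _fit_exponential(
    centers: np.ndarray, values: np.ndarray, pair_weights: np.ndarray
) -> tuple[float, float, float]:
    """Pair-count-weighted nonlinear LS of A0*exp(-lam*d) + c; lam >= 0."""
    c0 = float(np.mean(values[-max(3, len(values) // 5):]))
    a0 = float(values[0] - c0)
    if a0 <= 0:
        a0 = max(abs(a0), 1e-6)
    span = centers[-1] - centers[0]
    lam0 = min(max(1.0 / max(span / 3.0, 1e-6), 1.0), 500.0)
    sigma = 1.0 / np.sqrt(pair_weights)

    def model(d, a, lam, c):
        return a * np.exp(-lam * d) + c

    try:
        popt, _ = curve_fit(
            model,
            centers,
            values,
            p0=(a0, lam0, c0),
            sigma=sigma,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, 2000.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"decay fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_decay(
    curve: AncestryCovarianceCurve,
    fit_lo: float = DEFAULT_FIT_LO_M,
    fit_hi: float | None = None,
) -> DateFit:
    """Fit A0*exp(-lambda*d) + c to the covariance curve over bins in
    [fit_lo, fit_hi], weighting bins by pair counts. ``lambda`` (per Morgan)
    is the generations-since-admixture estimate; its SE comes from refitting
    with each chromosome's contribution deleted (weighted jackknife over
    chromosomes, weights = deleted pair mass)."""
    if fit_hi is None:
        fit_hi = float(curve.bin_centers[-1] + 1e-12)
    in_range = (curve.bin_centers >= fit_lo) & (curve.bin_centers <= fit_hi)
    usable = in_range & (curve.n_pairs > 0)
    if usable.sum() < 5:
        raise ValueError("need at least 5 usable bins in the fit range")
    centers = curve.bin_centers[usable]
    a0, lam, c = _fit_exponential(
        centers, curve.cov[usable], curve.n_pairs[usable].astype(float)
    )

    n_chrom = len(curve.chrom_labels)
    loo = []
    weights = []
    tot_sums = curve.chrom_sums.sum(axis=0)
    tot_pairs = curve.chrom_pairs.sum(axis=0)
    for ci in range(n_chrom):
        pairs_j = tot_pairs - curve.chrom_pairs[ci]
        use_j = in_range & (pairs_j > 0)
        if use_j.sum() < 5:
            continue
        vals_j = (tot_sums - curve.chrom_sums[ci])[use_j] / pairs_j[use_j]
        try:
            _, lam_j, _ = _fit_exponential(
                curve.bin_centers[use_j], vals_j, pairs_j[use_j].astype(float)
            )
        except ValueError:
            continue
        loo.append(lam_j)
        weights.append(curve.chrom_pairs[ci][in_range].sum())
    if len(loo) < 2:
        raise ValueError("too few chromosomes for jackknife SE")
    jk = weighted_jackknife(lam, np.array(loo), np.array(weights, dtype=float))
    return DateFit(
        amplitude=a0,
        rate=lam,
        affine=c,
        t_se=jk.se,
        fit_lo=fit_lo,
        fit_hi=fit_hi,
        n_chromosomes=len(loo),
        at_bound=lam < 1e-9,
    )


def to_calendar(
    fit: DateFit | tuple[float, float],
    generation_time: float = 30.0,
    sample_age_bp: float = 0.0,
) -> CalendarDate:
    """Convert generations since admixture to calendar years BP:
    years = sample_age_BP + t * generation_time, SE = SE_t * generation_time.

    ``fit`` is a :class:`DateFit` or a plain (t, t_se) tuple.
    """
    if sample_age_bp < 0:
        raise ValueError("sample age must be >= 0")
    if isinstance(fit, DateFit):
        t, t_se = fit.t_generations, fit.t_se
    else:
        t, t_se = fit
    return CalendarDate(
        years_bp=sample_age_bp + t * generation_time,
        se_years=t_se * generation_time,
        generation_time=generation_time,
        sample_age_bp=sample_age_bp,
    )


def curve_table(curve: AncestryCovarianceCurve):
    """TSV-ready table (bin_center_cM, cov, n_pairs)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "bin_center_cM": curve.bin_centers * 100.0,
            "cov": curve.cov,
            "n_pairs": curve.n_pairs,
        }
    )
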