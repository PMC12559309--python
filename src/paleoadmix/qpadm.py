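"""qpAdm-style admixture modelling.

Models a target population/individual as a mixture of source ("left")
populations such that all f4 relations to a set of reference ("right")
populations are satisfied. The estimand is the generalised-least-squares
solution on f4 profiles:

    e(a) = profile(target) - sum_i a_i * profile(source_i),  sum_i a_i = 1

where profile(L)_j = mean over sites of (p_L - p_R1)(p_{R_{j+1}} - p_R1) and
the error covariance C of e comes from a weighted block jackknife. The fit
statistic T = min_a e'C^{-1}e is chi^2 with df = |rights| - |sources| under
the model; nested models are compared through the difference of fit
statistics, and a coverage-downsampling experiment checks robustness of the
model choice to read depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import genodata
from .fstats import BlockPartition, weighted_jackknife
from .genodata import AlleleFrequencyTable, GenotypeMatrix, PileupTable


@dataclass(frozen=True)
class AdmixtureModel:
    """Target, ordered sources (2 or 3 typical) and rights; ``rights[0]`` is
    the base right population."""

    target: str
    sources: tuple[str, ...]
    rights: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "rights", tuple(self.rights))
        pools = set(self.sources) | set(self.rights)
        if self.target in pools:
            raise ValueError("target may not appear among sources or rights")
        if set(self.sources) & set(self.rights):
            raise ValueError("sources and rights overlap")
        if len(self.rights) < len(self.sources) + 1:
            raise ValueError("need at least |sources| + 1 right populations")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AdmixtureModel":
        return cls(d["target"], tuple(d["sources"]), tuple(d["rights"]))


@dataclass
class F4Profile:
    left: str
    rights: tuple[str, ...]
    values: np.ndarray  # (R-1,)
    block_sums: np.ndarray = field(repr=False)  # (g, R-1)
    block_counts: np.ndarray = field(repr=False)  # (g,) usable sites per block


@dataclass
class AdmixtureFit:
    model: AdmixtureModel
    weights: np.ndarray
    weight_se: np.ndarray
    t_stat: float
    df: int
    p_value: float
    feasible: bool
    n_sites: int
    n_blocks: int
    ridge: float = 0.0
    loo_weights: np.ndarray | None = field(default=None, repr=False)
    # converged profiles and covariance, kept for nested-model comparisons
    profile_target: np.ndarray | None = field(default=None, repr=False)
    profile_sources: np.ndarray | None = field(default=None, repr=False)
    cov_e: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": list(self.model.sources),
                "weight": self.weights,
                "se": self.weight_se,
            }
        )

    def to_dict(self) -> dict:
        return {
            "target": self.model.target,
            "sources": list(self.model.sources),
            "rights": list(self.model.rights),
            "weights": [float(w) for w in self.weights],
            "weight_se": [float(s) for s in self.weight_se],
            "T": float(self.t_stat),
            "df": int(self.df),
            "P": float(self.p_value),
            "feasible": bool(self.feasible),
            "n_sites": int(self.n_sites),
            "n_blocks": int(self.n_blocks),
        }


@dataclass
class NestedComparison:
    full: AdmixtureFit
    reduced: AdmixtureFit
    delta_t: float
    df: int
    p_value: float


@dataclass
class DownsamplingReport:
    n_reps: int
    replicates: pd.DataFrame  # rep, seeds, P2, P3, nested P, weights
    n_pass_two_way: int
    n_pass_three_way: int
    n_nested_reject: int
    errors: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# f4 profiles
# ---------------------------------------------------------------------------


def _profile_arrays(
    freqs: AlleleFrequencyTable,
    lefts: Sequence[str],
    rights: Sequence[str],
    blocks: BlockPartition,
    mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block f4-profile sums for each left population on a common site
    mask. Returns (block_sums (g, K, R-1), block_counts (g,), totals)."""
    g = blocks.n_blocks
    base = freqs.column(rights[0])
    d_r = np.column_stack([freqs.column(r) - base for r in rights[1:]])
    cnt = np.bincount(blocks.block_index, weights=mask.astype(float), minlength=g)
    sums = np.zeros((g, len(lefts), len(rights) - 1))
    for k, left in enumerate(lefts):
        u = (freqs.column(left) - base)[:, None] * d_r
        u = np.where(mask[:, None], u, 0.0)
        for c in range(d_r.shape[1]):
            sums[:, k, c] = np.bincount(
                blocks.block_index, weights=u[:, c], minlength=g
            )
    return sums, cnt, sums.sum(axis=0)


def _complete_case_mask(freqs: AlleleFrequencyTable, pops: Sequence[str]) -> np.ndarray:
    p = freqs.columns(list(pops))
    return ~np.isnan(p).any(axis=1)


def f4_profile(
    freqs: AlleleFrequencyTable,
    left_pop: str,
    rights: Sequence[str],
    blocks: BlockPartition,
) -> F4Profile:
    """f4(left, R1; R_{j+1}, R1) for j = 1..R-1 as per-site means of
    (p_left - p_R1)(p_{R_{j+1}} - p_R1), with per-block sums retained for
    jackknife covariance. Sites missing in the left or any right population
    are dropped."""
    rights = tuple(rights)
    if len(rights) < 2:
        raise ValueError("need at least 2 right populations")
    mask = _complete_case_mask(freqs, (left_pop, *rights))
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"no usable sites for f4 profile of {left_pop} vs {rights}"
        )
    sums, cnt, totals = _profile_arrays(freqs, [left_pop], rights, blocks, mask)
    values = totals[0] / n
    return F4Profile(left_pop, rights, values, sums[:, 0, :], cnt)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _joint_jackknife_cov(
    theta_full: np.ndarray, theta_loo: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted block-jackknife covariance of a vector statistic via
    pseudovalues (multivariate analogue of the scalar weighted jackknife)."""
    g, dim = theta_loo.shape
    n = weights.sum()
    h = (n / weights)[:, None]
    tau = h * theta_full[None, :] - (h - 1.0) * theta_loo
    theta_j = g * theta_full - ((1.0 - weights[:, None] / n) * theta_loo).sum(axis=0)
    dev = tau - theta_j[None, :]
    scaled = dev / np.sqrt(h - 1.0)
    return (scaled.T @ scaled) / g


def _regularize(c: np.ndarray) -> tuple[np.ndarray, float]:
    """Return a positive-definite version of ``c``; escalating ridge if the
    Cholesky factorisation fails."""
    dim = c.shape[0]
    base = max(np.trace(c) / dim, 1e-30)
    ridge = 0.0
    eps = 1e-9
    for _ in range(25):
        try:
            np.linalg.cholesky(c + ridge * np.eye(dim))
            return c + ridge * np.eye(dim), ridge
        except np.linalg.LinAlgError:
            ridge = eps * base
            eps *= 10.0
    raise np.linalg.LinAlgError("covariance cannot be regularized")


def _solve_weights(
    y: np.ndarray, x: np.ndarray, c_inv_mul, s: int
) -> np.ndarray:
    """Constrained GLS: minimise (y - X a)' C^-1 (y - X a) s.t. sum(a) = 1,
    by eliminating the last weight."""
    x_last = x[:, s - 1]
    xt = x[:, : s - 1] - x_last[:, None]
    yt = y - x_last
    a_mat = xt.T @ c_inv_mul(xt)
    b_vec = xt.T @ c_inv_mul(yt)
    if s == 1:
        return np.array([1.0])
    b = np.linalg.solve(a_mat, b_vec)
    return np.concatenate([b, [1.0 - np.sum(b)]])


def fit_admixture(
    model: AdmixtureModel,
    freqs: AlleleFrequencyTable,
    blocks: BlockPartition,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> AdmixtureFit:
    """Fit admixture weights for ``model`` by constrained GLS on f4 profiles.

    Only sites non-missing in the target, every source and every right are
    used ("complete cases"). The covariance C of e(a) is the weighted block
    jackknife covariance of the profile combination and is re-evaluated at
    the current weights until convergence. Weights are constrained to sum to
    1 but may exit [0, 1]; feasibility is reported, never enforced. Weight
    SEs come from per-deleted-block refits (C held fixed). A singular C is
    ridge-regularised with a warning.
    """
    lefts = (model.target, *model.sources)
    s = len(model.sources)
    r = len(model.rights)
    df = r - s
    mask = _complete_case_mask(freqs, (*lefts, *model.rights))
    n_sites = int(mask.sum())
    if n_sites == 0:
        raise ValueError("no sites shared by all model populations")
    sums, cnt, totals = _profile_arrays(freqs, lefts, model.rights, blocks, mask)
    nonempty = cnt > 0
    sums = sums[nonempty]
    cnt = cnt[nonempty]
    g = int(nonempty.sum())
    if g < df + 1:
        raise ValueError(f"only {g} usable blocks for df={df}")
    n_tot = cnt.sum()
    k = len(lefts)
    dim = r - 1
    full_profiles = totals / n_tot  # (K, R-1)
    loo_profiles = (totals[None, :, :] - sums) / (n_tot - cnt)[:, None, None]

    theta_full = full_profiles.reshape(-1)
    theta_loo = loo_profiles.reshape(g, -1)
    cov = _joint_jackknife_cov(theta_full, theta_loo, cnt.astype(float))
    cov4 = cov.reshape(k, dim, k, dim)

    y = full_profiles[0]
    x = full_profiles[1:].T  # (R-1, S)

    a = np.full(s, 1.0 / s)
    ridge_used = 0.0
    c_reg = np.eye(dim)
    for _ in range(max_iter):
        coef = np.concatenate([[1.0], -a])
        c = np.einsum("i,iajb,j->ab", coef, cov4, coef)
        c_reg, ridge = _regularize(c)
        ridge_used = max(ridge_used, ridge)
        c_inv_mul = lambda v: np.linalg.solve(c_reg, v)
        a_new = _solve_weights(y, x, c_inv_mul, s)
        if np.max(np.abs(a_new - a)) < tol:
            a = a_new
            break
        a = a_new
    if ridge_used > 0:
        warnings.warn(
            f"singular f4 covariance; ridge {ridge_used:.3e} applied",
            RuntimeWarning,
            stacklevel=2,
        )
    e = y - x @ a
    t_stat = float(e @ np.linalg.solve(c_reg, e))
    p_value = float(stats.chi2.sf(t_stat, df))

    # weight SEs: refit per deleted block with C fixed at the converged value
    loo_w = np.zeros((g, s))
    for j in range(g):
        prof_j = loo_profiles[j]
        y_j = prof_j[0]
        x_j = prof_j[1:].T
        loo_w[j] = _solve_weights(y_j, x_j, lambda v: np.linalg.solve(c_reg, v), s)
    weight_se = np.zeros(s)
    for i in range(s):
        jk = weighted_jackknife(float(a[i]), loo_w[:, i], cnt.astype(float))
        weight_se[i] = jk.se

    feasible = bool(np.all((a >= -1e-9) & (a <= 1 + 1e-9)))
    return AdmixtureFit(
        model=model,
        weights=a,
        weight_se=weight_se,
        t_stat=max(t_stat, 0.0),
        df=df,
        p_value=p_value,
        feasible=feasible,
        n_sites=n_sites,
        n_blocks=g,
        ridge=ridge_used,
        loo_weights=loo_w,
        profile_target=y,
        profile_sources=x,
        cov_e=c_reg,
    )


def nested_model_test(full: AdmixtureFit, reduced: AdmixtureFit) -> NestedComparison:
    """Likelihood-ratio-style comparison of a reduced model nested in a full
    model: delta T = T_reduced - T_full, P from chi^2 with df = number of
    dropped sources.

    Both fit statistics are evaluated under the full model's converged error
    covariance (the standard GLS likelihood-ratio construction): the reduced
    model's weights are re-solved in that common metric, which makes delta T
    an exact nested-projection difference, non-negative by construction.
    When the fits were made on different site sets (so the stored profiles
    are not comparable) the plain difference of the reported T statistics is
    used instead, clamped at 0.
    """
    if full.model.target != reduced.model.target:
        raise ValueError("nested models must share the target")
    if tuple(full.model.rights) != tuple(reduced.model.rights):
        raise ValueError("nested models must share the right populations")
    if not set(reduced.model.sources) <= set(full.model.sources):
        raise ValueError("reduced sources are not a subset of full sources")
    df = len(full.model.sources) - len(reduced.model.sources)
    if df == 0:
        return NestedComparison(full, reduced, 0.0, 0, 1.0)

    comparable = (
        full.profile_target is not None
        and full.cov_e is not None
        and full.n_sites == reduced.n_sites
    )
    if comparable:
        y = full.profile_target
        cols = [full.model.sources.index(s) for s in reduced.model.sources]
        x_red = full.profile_sources[:, cols]
        c_inv_mul = lambda v: np.linalg.solve(full.cov_e, v)
        a_red = _solve_weights(y, x_red, c_inv_mul, len(cols))
        e_red = y - x_red @ a_red
        t_red = float(e_red @ np.linalg.solve(full.cov_e, e_red))
        delta = t_red - full.t_stat
    else:
        delta = reduced.t_stat - full.t_stat
    if delta < -1e-6 * max(1.0, full.t_stat):
        warnings.warn(
            f"nested delta T is negative ({delta:.3g}); clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    delta = max(delta, 0.0)
    return NestedComparison(full, reduced, delta, df, float(stats.chi2.sf(delta, df)))


# ---------------------------------------------------------------------------
# Downsampling experiment
# ---------------------------------------------------------------------------


def with_individual(
    freqs: AlleleFrequencyTable,
    label: str,
    calls: np.ndarray,
    pseudo_haploid: bool = True,
) -> AlleleFrequencyTable:
    """Return a frequency table extended by a single-individual population
    built from a call vector (same site order)."""
    calls = np.asarray(calls)
    if len(calls) != freqs.freq.shape[0]:
        raise ValueError("call vector length does not match site count")
    obs = calls != genodata.MISSING
    p = np.where(obs, calls / 2.0, np.nan)
    n = obs.astype(np.int64) * (1 if pseudo_haploid else 2)
    return AlleleFrequencyTable(
        freqs.populations + [label],
        np.column_stack([freqs.freq, p]),
        np.column_stack([freqs.n, n]),
        freqs.snps,
    )


def downsampling_experiment(
    target_pileups: PileupTable,
    panel_freqs: AlleleFrequencyTable,
    model2: AdmixtureModel,
    model3: AdmixtureModel,
    target_cov: float,
    blocks: BlockPartition,
    n_reps: int = 100,
    seed: int = 0,
) -> DownsamplingReport:
    """Repeatedly thin the target's pileups to ``target_cov``, re-call
    pseudo-haploid genotypes, and fit the two-way and three-way models plus
    their nested comparison; summarise how many replicates keep each model
    (P >= 0.05) and reject the reduced one (nested P < 0.05).

    Per-replicate failures are recorded without aborting the experiment.
    """
    if model2.target != model3.target:
        raise ValueError("models must share the target label")
    current_cov = target_pileups.mean_coverage()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(2**31 - 1, size=(max(n_reps, 1), 2))
    rows = []
    errors: list[str] = []
    for rep in range(n_reps):
        thin_seed, call_seed = int(rep_seeds[rep, 0]), int(rep_seeds[rep, 1])
        try:
            thinned = genodata.downsample_pileups(
                target_pileups, current_cov, min(target_cov, current_cov), thin_seed
            )
            calls = genodata.pseudo_haploid_call_all(thinned, call_seed)
            freqs = with_individual(panel_freqs, model2.target, calls)
            fit2 = fit_admixture(model2, freqs, blocks)
            fit3 = fit_admixture(model3, freqs, blocks)
            nested = nested_model_test(fit3, fit2)
            rows.append(
                {
                    "rep": rep,
                    "seed_thin": thin_seed,
                    "seed_call": call_seed,
                    "p_two_way": fit2.p_value,
                    "p_three_way": fit3.p_value,
                    "p_nested": nested.p_value,
                    "n_sites": fit3.n_sites,
                    **{
                        f"w3_{src}": float(wt)
                        for src, wt in zip(model3.sources, fit3.weights)
                    },
                }
            )
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            errors.append(f"rep {rep}: {exc}")
    table = pd.DataFrame(rows)
    if len(table):
        n2 = int((table["p_two_way"] >= 0.05).sum())
        n3 = int((table["p_three_way"] >= 0.05).sum())
        nn = int((table["p_nested"] < 0.05).sum())
    else:
        n2 = n3 = nn = 0
    return DownsamplingReport(n_reps, table, n2, n3, nn, errors)
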