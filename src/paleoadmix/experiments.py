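"""Replicated validation experiments on synthetic admixed genomes.

Each experiment rebuilds its dataset from the three-source admixture-graph
scenario (see :mod:`paleoadmix.simulate`), runs the corresponding inference
end to end, and reports summary numbers: two-way weight recovery with CI
coverage, nested-model power and type-I calibration, the coverage
downsampling robustness check, admixture-LD dating recovery, and the
transversion-replication rank concordance. All randomness derives from a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import admixdating, fstats, genodata, qpadm, simulate


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 1, size=n)


def _scenario(n_snps: int, seed: int):
    """Graph, SNP map, frequencies and jackknife blocks for one replicate."""
    graph = simulate.three_source_graph(n_snps=n_snps)
    snps = simulate.uniform_snp_map(n_snps, graph.chrom_lengths_m, seed=0)
    freqs_by_pop = simulate.simulate_frequencies(graph, seed)
    blocks = fstats.make_blocks(snps)
    return graph, snps, freqs_by_pop, blocks


def _pseudo_haploid_target(graph, freqs_by_pop, snps, alphas, sources, t_gen,
                           seed, mean_cov=1.0, damage_delta=0.0):
    truth, pileups = simulate.simulate_target_calls(
        graph, freqs_by_pop, snps, alphas, sources, t_gen, seed,
        mean_cov=mean_cov, damage_delta=damage_delta,
    )
    calls = genodata.pseudo_haploid_call_all(pileups, seed + 1)
    return truth, pileups, calls


@dataclass
class RecoveryResult:
    alpha_true: float
    alpha_hat: np.ndarray
    alpha_se: np.ndarray
    covered: np.ndarray

    @property
    def mean_alpha(self) -> float:
        return float(self.alpha_hat.mean())

    @property
    def coverage(self) -> float:
        return float(self.covered.mean())


def two_way_recovery(
    alpha: float = 0.3,
    n_reps: int = 100,
    n_snps: int = 50_000,
    t_generations: float = 25.0,
    mean_cov: float = 1.0,
    seed: int = 0,
) -> RecoveryResult:
    """Repeatedly simulate a two-way admixed pseudo-haploid target and refit
    its first-source weight; reports per-replicate estimates, jackknife SEs
    and whether the 95% CI covered the truth."""
    seeds = _rep_seeds(seed, n_reps)
    sources = simulate.SOURCES[:2]
    model = qpadm.AdmixtureModel("Target", sources, simulate.RIGHTS)
    hats, ses, cov = [], [], []
    for rep in range(n_reps):
        s = int(seeds[rep])
        graph, snps, fbp, blocks = _scenario(n_snps, s)
        _, _, calls = _pseudo_haploid_target(
            graph, fbp, snps, (alpha, 1 - alpha), sources, t_generations, s + 7,
            mean_cov=mean_cov,
        )
        table = simulate.frequency_table(
            {k: v for k, v in fbp.items() if not k.startswith("anc")}, snps
        )
        table = qpadm.with_individual(table, "Target", calls)
        fit = qpadm.fit_admixture(model, table, blocks)
        hats.append(fit.weights[0])
        ses.append(fit.weight_se[0])
        cov.append(abs(fit.weights[0] - alpha) <= 1.96 * fit.weight_se[0])
    return RecoveryResult(
        alpha, np.array(hats), np.array(ses), np.array(cov, dtype=bool)
    )


@dataclass
class NestedExperimentResult:
    p_two_way_fit: np.ndarray
    p_three_way_fit: np.ndarray
    p_nested: np.ndarray
    weights_three_way: np.ndarray

    @property
    def nested_reject_rate(self) -> float:
        return float((self.p_nested < 0.05).mean())

    @property
    def two_way_reject_rate(self) -> float:
        return float((self.p_two_way_fit < 0.05).mean())


def nested_experiment(
    alphas: tuple[float, float, float],
    n_reps: int,
    n_snps: int = 50_000,
    t_generations: float = 25.0,
    mean_cov: float = 1.0,
    seed: int = 0,
) -> NestedExperimentResult:
    """Fit the two-way and three-way models (and their nested comparison) to
    replicated targets with true three-way proportions ``alphas``; with a
    zero third proportion this doubles as the type-I calibration experiment
    for the nested test."""
    seeds = _rep_seeds(seed + 1, n_reps)
    sources3 = simulate.SOURCES
    sources2 = simulate.SOURCES[:2]
    model2 = qpadm.AdmixtureModel("Target", sources2, simulate.RIGHTS)
    model3 = qpadm.AdmixtureModel("Target", sources3, simulate.RIGHTS)
    p2, p3, pn, w3 = [], [], [], []
    for rep in range(n_reps):
        s = int(seeds[rep])
        graph, snps, fbp, blocks = _scenario(n_snps, s)
        a1, a2, a3 = alphas
        if a3 <= 0:
            _, _, calls = _pseudo_haploid_target(
                graph, fbp, snps, (a1 / (a1 + a2), a2 / (a1 + a2)), sources2,
                t_generations, s + 7, mean_cov=mean_cov,
            )
        else:
            _, _, calls = _pseudo_haploid_target(
                graph, fbp, snps, alphas, sources3, t_generations, s + 7,
                mean_cov=mean_cov,
            )
        table = simulate.frequency_table(
            {k: v for k, v in fbp.items() if not k.startswith("anc")}, snps
        )
        table = qpadm.with_individual(table, "Target", calls)
        fit2 = qpadm.fit_admixture(model2, table, blocks)
        fit3 = qpadm.fit_admixture(model3, table, blocks)
        nested = qpadm.nested_model_test(fit3, fit2)
        p2.append(fit2.p_value)
        p3.append(fit3.p_value)
        pn.append(nested.p_value)
        w3.append(fit3.weights)
    return NestedExperimentResult(
        np.array(p2), np.array(p3), np.array(pn), np.array(w3)
    )


def downsampling_robustness(
    alphas: tuple[float, float, float] = (0.20, 0.14, 0.66),
    high_cov: float = 4.0,
    low_cov: float = 1.0,
    n_reps: int = 20,
    n_snps: int = 50_000,
    t_generations: float = 25.0,
    seed: int = 0,
) -> qpadm.DownsamplingReport:
    """Scaled-down analogue of the coverage-downsampling robustness check: a
    strongly three-way target sequenced at ``high_cov`` is repeatedly
    thinned to ``low_cov``, re-called and refit under both models.

    Default proportions mirror a late-admixed genome with dominant
    third-source ancestry.
    """
    graph, snps, fbp, blocks = _scenario(n_snps, seed + 11)
    _, pileups = simulate.simulate_target_calls(
        graph, fbp, snps, alphas, simulate.SOURCES, t_generations, seed + 13,
        mean_cov=high_cov,
    )
    table = simulate.frequency_table(
        {k: v for k, v in fbp.items() if not k.startswith("anc")}, snps
    )
    model2 = qpadm.AdmixtureModel("Target", simulate.SOURCES[:2], simulate.RIGHTS)
    model3 = qpadm.AdmixtureModel("Target", simulate.SOURCES, simulate.RIGHTS)
    return qpadm.downsampling_experiment(
        pileups, table, model2, model3, low_cov, blocks, n_reps=n_reps,
        seed=seed + 17,
    )


@dataclass
class DatingResult:
    t_true: float
    t_hat: float
    t_se: float

    @property
    def within_2se(self) -> bool:
        return abs(self.t_hat - self.t_true) <= 2.0 * self.t_se


def dating_recovery(
    t_generations: float = 25.0,
    alpha: float = 0.5,
    n_snps: int = 50_000,
    mean_cov: float = 1.0,
    seed: int = 0,
    transversions_only: bool = False,
) -> DatingResult:
    """Simulate a tract-structured pseudo-haploid admixed genome and re-date
    the admixture pulse from its ancestry-covariance decay."""
    graph, snps, fbp, blocks = _scenario(n_snps, seed + 3)
    sources = simulate.SOURCES[:2]
    _, _, calls = _pseudo_haploid_target(
        graph, fbp, snps, (alpha, 1 - alpha), sources, t_generations, seed + 5,
        mean_cov=mean_cov,
    )
    table = simulate.frequency_table(
        {k: v for k, v in fbp.items() if not k.startswith("anc")}, snps
    )
    if transversions_only:
        keep = np.array(
            [i for i, s in enumerate(snps) if genodata.is_transversion(s)]
        )
        table = table.take_sites(keep)
        calls = np.asarray(calls)[keep]
        snps = [snps[i] for i in keep]
    curve = admixdating.ancestry_cov_curve(
        calls, table, sources[0], sources[1], snps=snps
    )
    fit = admixdating.fit_decay(curve)
    return DatingResult(t_generations, fit.t_generations, fit.t_se)


def dating_monotonicity(
    t_values: tuple[float, ...] = (5.0, 15.0, 25.0, 50.0),
    n_reps: int = 5,
    n_snps: int = 50_000,
    seed: int = 0,
) -> dict[float, float]:
    """Mean fitted admixture age per simulated age; used to check that the
    dating estimator orders admixture times correctly."""
    out: dict[float, float] = {}
    for ti, t_gen in enumerate(t_values):
        hats = [
            dating_recovery(t_gen, seed=seed + 1000 * ti + r, n_snps=n_snps).t_hat
            for r in range(n_reps)
        ]
        out[t_gen] = float(np.mean(hats))
    return out


def transversion_concordance(
    n_snps: int = 50_000,
    damage_delta: float = 0.1,
    mean_cov: float = 1.0,
    seed: int = 0,
) -> float:
    """Spearman rank concordance between the all-site and transversion-only
    outgroup-f3 affinity scans of a damaged pseudo-haploid target."""
    graph, snps, fbp, blocks = _scenario(n_snps, seed + 23)
    _, _, calls = _pseudo_haploid_target(
        graph, fbp, snps, (0.5, 0.5), simulate.SOURCES[:2], 25.0, seed + 29,
        mean_cov=mean_cov, damage_delta=damage_delta,
    )
    table = simulate.frequency_table(
        {k: v for k, v in fbp.items() if not k.startswith("anc")}, snps
    )
    table = qpadm.with_individual(table, "Target", calls)
    candidates = [p for p in table.populations
                  if p not in (simulate.OUTGROUP, "Target")]
    scan_all = fstats.outgroup_f3_scan(
        table, "Target", candidates, simulate.OUTGROUP, blocks
    )
    keep = np.array([i for i, s in enumerate(snps) if genodata.is_transversion(s)])
    table_tv = table.take_sites(keep)
    blocks_tv = fstats.make_blocks([snps[i] for i in keep])
    scan_tv = fstats.outgroup_f3_scan(
        table_tv, "Target", candidates, simulate.OUTGROUP, blocks_tv
    )
    a = scan_all.set_index("population")["f3"]
    b = scan_tv.set_index("population")["f3"]
    shared = a.index.intersection(b.index)
    return fstats.rank_concordance(a[shared].to_numpy(), b[shared].to_numpy())
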