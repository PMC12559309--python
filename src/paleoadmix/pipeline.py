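"""End-to-end analysis orchestration.

Runs the full admixture-inference scaffold on any conforming dataset (real
or synthetic): outgroup-f3 affinity scans, PCA projection, D-statistic
scans, pairwise-f3 deviation regression, qpAdm model fits with nested
tests, transversion-only replication with rank concordance, an optional
coverage-downsampling experiment, and admixture-LD dating with calendar
conversion. Stages run in a fixed order; a failing stage is recorded and
later independent stages still run. One summary JSON collects every
statistic with its SE/Z/P and the seed, and validates against the shipped
schema.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import admixdating, fstats, genodata, pcaproj, qpadm
from .genodata import GenotypeMatrix, PileupTable

log = logging.getLogger("paleoadmix")

STAGES = (
    "f3_scan",
    "pca",
    "d_scan",
    "pairwise_f3",
    "qpadm",
    "transversion_replication",
    "downsampling",
    "dating",
)


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    outgroup: str
    targets: list[str]
    candidates: list[str]
    qpadm_models: list[dict] = field(default_factory=list)  # name/target/sources/rights
    geno: str | None = None
    snp: str | None = None
    ind: str | None = None
    pileup_tsv: str | None = None
    pileup_target: str | None = None
    site_filter: str = "all"  # all | transversions
    dating: dict | None = None  # target, source_a, source_b, generation_time, sample_age_bp
    downsampling: dict | None = None  # target_cov, current_cov, n_reps, model2, model3
    block_size_m: float = fstats.DEFAULT_BLOCK_SIZE_M
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid analysis config: {exc}") from exc

    def validate(self, matrix: GenotypeMatrix) -> None:
        pops = set(matrix.populations)
        unknown = ({self.outgroup} | set(self.targets) | set(self.candidates)) - pops
        if unknown:
            raise ValueError(f"labels not in panel: {sorted(unknown)}")
        if self.site_filter not in ("all", "transversions"):
            raise ValueError("site_filter must be 'all' or 'transversions'")


def _stage(summary: dict, name: str, func) -> None:
    try:
        summary["stages"][name] = {"status": "ok", **func()}
    except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
        log.error("stage %s failed: %s", name, exc)
        summary["stages"][name] = {"status": "error", "error": str(exc)}


def _f3_block(freqs, outgroup, targets, candidates, blocks) -> dict:
    out = {}
    for target in targets:
        cands = [c for c in candidates if c != target]
        table = fstats.outgroup_f3_scan(freqs, target, cands, outgroup, blocks)
        for row in table.itertuples():
            log.info(
                "f3(%s; %s, %s): n=%d est=%.6g se=%.3g z=%.2f",
                outgroup, target, row.population, row.n_sites, row.f3, row.se, row.z,
            )
        out[target] = table.to_dict(orient="records")
    return {"scans": out}


def _qpadm_block(freqs, models, blocks) -> dict:
    fits: dict[str, qpadm.AdmixtureFit] = {}
    results = {}
    for spec in models:
        model = qpadm.AdmixtureModel.from_dict(spec)
        fit = qpadm.fit_admixture(model, freqs, blocks)
        fits[spec.get("name", "+".join(model.sources))] = fit
        results[spec.get("name", "+".join(model.sources))] = fit.to_dict()
        log.info(
            "qpAdm %s <- %s: T=%.3f df=%d P=%.4g weights=%s",
            model.target, model.sources, fit.t_stat, fit.df, fit.p_value,
            np.round(fit.weights, 4).tolist(),
        )
    nested = []
    for name_f, fit_f in fits.items():
        for name_r, fit_r in fits.items():
            if (
                fit_f.model.target == fit_r.model.target
                and fit_f.model.rights == fit_r.model.rights
                and set(fit_r.model.sources) < set(fit_f.model.sources)
            ):
                cmp_ = qpadm.nested_model_test(fit_f, fit_r)
                nested.append(
                    {
                        "full": name_f,
                        "reduced": name_r,
                        "delta_T": cmp_.delta_t,
                        "df": cmp_.df,
                        "P": cmp_.p_value,
                    }
                )
    return {"fits": results, "nested": nested}


def run_analysis(
    config: AnalysisConfig,
    matrix: GenotypeMatrix | None = None,
    pileups: PileupTable | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute every stage of the analysis scaffold; returns (and optionally
    writes) the summary dictionary."""
    if matrix is None:
        if not (config.geno and config.snp and config.ind):
            raise ValueError("config must provide geno/snp/ind paths or a matrix")
        matrix = genodata.read_eigenstrat(config.geno, config.snp, config.ind)
    if pileups is None and config.pileup_tsv:
        pileups = genodata.read_pileup_tsv(config.pileup_tsv, matrix.snps)
    config.validate(matrix)
    if config.site_filter == "transversions":
        matrix = genodata.filter_transversions(matrix)

    freqs = genodata.allele_frequencies(matrix)
    blocks = fstats.make_blocks(matrix.snps, config.block_size_m)
    summary: dict[str, Any] = {
        "seed": config.seed,
        "n_sites": matrix.n_sites,
        "n_individuals": matrix.n_individuals,
        "site_filter": config.site_filter,
        "stages": {},
    }

    _stage(
        summary,
        "f3_scan",
        lambda: _f3_block(freqs, config.outgroup, config.targets,
                          config.candidates, blocks),
    )

    def pca_block() -> dict:
        target_set = set(config.targets)
        ref_cols = [
            j for j, ind in enumerate(matrix.individuals)
            if ind.population not in target_set
        ]
        ref = GenotypeMatrix(
            matrix.snps, [matrix.individuals[j] for j in ref_cols],
            matrix.calls[:, ref_cols],
        )
        model = pcaproj.fit_pca(ref, n_components=2)
        projections = {}
        for j, ind in enumerate(matrix.individuals):
            if ind.population in target_set:
                coords = pcaproj.project_sample(model, matrix.calls[:, j])
                projections[ind.ind_id] = [float(c) for c in coords]
        return {
            "eigenvalues": [float(v) for v in model.eigenvalues],
            "reference": model.coordinates.to_dict(orient="records"),
            "projections": projections,
        }

    _stage(summary, "pca", pca_block)

    def d_block() -> dict:
        if len(config.targets) < 2:
            return {"status_note": "needs two targets", "scans": {}}
        t_a, t_b = config.targets[:2]
        rows = []
        for cand in config.candidates:
            if cand in (t_a, t_b):
                continue
            res = fstats.d_stat(freqs, config.outgroup, cand, t_a, t_b, blocks)
            log.info(
                "D(%s, %s; %s, %s): n=%d est=%.6g z=%.2f",
                config.outgroup, cand, t_a, t_b, res.n_sites, res.estimate,
                res.jackknife.z,
            )
            rows.append(
                {
                    "population": cand,
                    "D": res.estimate,
                    "se": res.jackknife.se,
                    "z": res.jackknife.z,
                    "n_sites": res.n_sites,
                }
            )
        return {"scans": {f"{t_a}|{t_b}": rows}}

    _stage(summary, "d_scan", d_block)

    def pairwise_block() -> dict:
        if len(config.targets) < 2:
            return {"status_note": "needs two targets"}
        t_a, t_b = config.targets[:2]
        cands = [c for c in config.candidates if c not in (t_a, t_b)]
        reg = fstats.pairwise_f3_regression(
            freqs, config.outgroup, t_a, t_b, cands, blocks
        )
        return {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "deviations": reg.table.to_dict(orient="records"),
        }

    _stage(summary, "pairwise_f3", pairwise_block)

    _stage(summary, "qpadm", lambda: _qpadm_block(freqs, config.qpadm_models, blocks))

    def transversion_block() -> dict:
        if config.site_filter == "transversions":
            # primary run already transversion-only; replication is identical
            rep: dict[str, Any] = {}
            for key in ("f3_scan", "d_scan", "qpadm"):
                rep[key] = summary["stages"].get(key, {})
            rep["rank_concordance"] = {
                t: 1.0 for t in config.targets
            }
            return rep
        tv = genodata.filter_transversions(matrix)
        freqs_tv = genodata.allele_frequencies(tv)
        blocks_tv = fstats.make_blocks(tv.snps, config.block_size_m)
        rep = {}
        rep["f3_scan"] = _f3_block(
            freqs_tv, config.outgroup, config.targets, config.candidates, blocks_tv
        )
        rep["qpadm"] = _qpadm_block(freqs_tv, config.qpadm_models, blocks_tv)
        rho = {}
        for target in config.targets:
            all_rows = summary["stages"]["f3_scan"]["scans"].get(target, [])
            tv_rows = rep["f3_scan"]["scans"].get(target, [])
            a = {r["population"]: r["f3"] for r in all_rows}
            b = {r["population"]: r["f3"] for r in tv_rows}
            shared = sorted(set(a) & set(b))
            if len(shared) >= 3:
                rho[target] = fstats.rank_concordance(
                    np.array([a[p] for p in shared]),
                    np.array([b[p] for p in shared]),
                )
            else:
                rho[target] = float("nan")
        rep["rank_concordance"] = rho
        return rep

    _stage(summary, "transversion_replication", transversion_block)

    def downsampling_block() -> dict:
        if pileups is None or not config.downsampling:
            return {"status_note": "skipped: no pileups provided"}
        ds = config.downsampling
        model2 = qpadm.AdmixtureModel.from_dict(ds["model2"])
        model3 = qpadm.AdmixtureModel.from_dict(ds["model3"])
        panel_pops = [
            p for p in freqs.populations if p != model2.target
        ]
        panel_freqs = genodata.AlleleFrequencyTable(
            panel_pops,
            freqs.columns(panel_pops),
            np.column_stack([freqs.n[:, freqs.populations.index(p)] for p in panel_pops]),
            freqs.snps,
        )
        report = qpadm.downsampling_experiment(
            pileups, panel_freqs, model2, model3,
            ds["target_cov"], blocks, n_reps=ds.get("n_reps", 100),
            seed=config.seed,
        )
        return {
            "n_reps": report.n_reps,
            "n_pass_two_way": report.n_pass_two_way,
            "n_pass_three_way": report.n_pass_three_way,
            "n_nested_reject": report.n_nested_reject,
            "errors": report.errors,
            "replicates": report.replicates.to_dict(orient="records"),
        }

    _stage(summary, "downsampling", downsampling_block)

    def dating_block() -> dict:
        if not config.dating:
            return {"status_note": "skipped: no dating config"}
        d = config.dating
        target = d["target"]
        col = [i.ind_id for i in matrix.individuals].index(target) if target in [
            i.ind_id for i in matrix.individuals
        ] else None
        if col is None:
            raise ValueError(f"dating target individual {target!r} not found")
        calls = matrix.calls[:, col]
        curve = admixdating.ancestry_cov_curve(
            calls, freqs, d["source_a"], d["source_b"], snps=matrix.snps
        )
        fit = admixdating.fit_decay(curve)
        cal = admixdating.to_calendar(
            fit, d.get("generation_time", 30.0), d.get("sample_age_bp", 0.0)
        )
        log.info(
            "dating %s: t=%.1f +- %.1f generations -> %.0f +- %.0f BP",
            target, fit.t_generations, fit.t_se, cal.years_bp, cal.se_years,
        )
        return {
            **fit.to_dict(),
            "years_bp": cal.years_bp,
            "se_years": cal.se_years,
            "generation_time": cal.generation_time,
            "sample_age_bp": cal.sample_age_bp,
        }

    _stage(summary, "dating", dating_block)

    validate_summary(summary)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_jsonify)
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_schema() -> dict:
    with resources.files("paleoadmix").joinpath("summary_schema.json").open() as fh:
        return json.load(fh)


def validate_summary(summary: Mapping) -> None:
    """Minimal structural validation of a summary dict against the shipped
    schema (required keys and primitive types)."""
    schema = load_schema()
    for key, expected in schema["required"].items():
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
        actual = summary[key]
        type_map = {"integer": (int, np.integer), "string": str, "object": dict}
        if not isinstance(actual, type_map[expected]):
            raise ValueError(f"summary key {key!r} has wrong type")
    for stage in STAGES:
        if stage not in summary["stages"]:
            raise ValueError(f"summary missing stage {stage!r}")
        if "status" not in summary["stages"][stage]:
            raise ValueError(f"stage {stage!r} lacks a status")
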