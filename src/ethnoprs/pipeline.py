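"""End-to-end orchestration of the stratified risk-modeling workflow.

One config drives: cohort simulation (or loading), QC, per-population
heritability estimation and SNP screening, nested-CV model selection,
between/within-population overlap analysis, pairwise cross-population
external validation, and the deviance decomposition of each population's
best model. All artifacts are plain TSV/JSON under the output directory,
plus a manifest with seeds and content hashes so identical config + seed
reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genio
from .decomposition import variable_contributions
from .mixed_model import KEig, compute_grm, reml_fit
from .prediction import CVPlan, cross_validate_pipeline, external_validate, model_to_dict
from .screening import ScreenCriterion, overlap_between_groups, screen_cohort, within_group_overlap
from .synthetic import SimulationConfig, make_populations, simulate_cohort

log = logging.getLogger("ethnoprs")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulation: dict | None = None  # SimulationConfig fields + populations block
    inputs: list[dict] | None = None  # [{label, geno_prefix, pheno_path}]
    qc: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    screening: dict = field(default_factory=lambda: {"criterion": "abs_blup", "p": 100, "within_splits": 3})
    decomposition: dict = field(default_factory=lambda: {"mode": "out_of_fold"})
    covariates: tuple[str, ...] = ("age", "sex", "pack_years")
    screen_covariates: tuple[str, ...] = ("age", "sex", "height", "pack_years")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of {simulation, inputs}")


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_groups(config: PipelineConfig) -> list[tuple[str, genio.GenotypeMatrix, pd.DataFrame]]:
    if config.simulation is not None:
        sim = dict(config.simulation)
        pops_block = sim.pop("populations")
        sim_cfg = SimulationConfig(seed=config.seed, **sim)
        pops = make_populations(
            sim_cfg,
            [b["label"] for b in pops_block],
            [int(b["n_samples"]) for b in pops_block],
            [float(b["case_fraction"]) for b in pops_block],
        )
        cohorts = simulate_cohort(sim_cfg, pops)
        return [(c.truth["label"], c.genotypes, c.phenotypes) for c in cohorts]
    out = []
    for block in config.inputs:
        g = genio.read_genotypes(block["geno_prefix"], block.get("dialect", "plink_bed"))
        phen = genio.read_phenotypes(block["pheno_path"])
        out.append((block["label"], g, phen))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}, "failed_stage": None}

    def record(path: Path) -> None:
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)

    thresholds = genio.QCThresholds(**config.qc)
    plan = CVPlan(seed=config.seed, **config.cv)
    crit = ScreenCriterion(config.screening.get("criterion", "abs_blup"), int(config.screening.get("p", 100)))

    try:
        groups = _load_groups(config)
        manifest["stages"].append("load")
        qcd = []
        for label, g, phen in groups:
            gdir = out / label
            gdir.mkdir(exist_ok=True)
            log.info("%s: %d samples x %d variants before QC", label, g.n_samples, g.n_variants)
            g, snp_report = genio.snp_qc_filter(g, thresholds)
            g, phen, sample_report = genio.sample_qc_filter(g, phen, thresholds)
            log.info("%s: %d samples x %d variants after QC", label, g.n_samples, g.n_variants)
            (gdir / "qc_report.json").write_text(
                json.dumps({"variants": json.loads(snp_report.to_json()), "samples": json.loads(sample_report.to_json())})
            )
            record(gdir / "qc_report.json")
            qcd.append((label, g, phen))
        if len(qcd) >= 2:
            # restrict every group to the allele-harmonized shared panel so
            # screening lists and external validation live on one universe
            mats, _log = genio.intersect_variants([g for _, g, _ in qcd])
            qcd = [(label, m, phen) for (label, _, phen), m in zip(qcd, mats)]
            log.info("shared panel after intersection: %d variants", mats[0].n_variants)
        per_group = {}
        for label, g, phen in qcd:
            gdir = out / label
            y = phen["trait"].to_numpy(dtype=float)
            Z = np.column_stack(
                [np.ones(len(phen))] + [phen[c].to_numpy(dtype=float) for c in config.screen_covariates]
            )
            grm = compute_grm(g)
            vc, _ = reml_fit(y, Z, grm, eig=KEig.from_grm(grm))
            (gdir / "heritability.json").write_text(
                json.dumps(
                    {
                        "h2": vc.h2,
                        "sigma_g2": vc.sigma_g2,
                        "sigma_e2": vc.sigma_e2,
                        "loglik": vc.loglik,
                        "converged": vc.converged,
                    }
                )
            )
            record(gdir / "heritability.json")

            top = screen_cohort(g, phen, crit, list(config.screen_covariates), source=label)
            pd.DataFrame({"rank": np.arange(1, len(top.variant_ids) + 1), "id": top.variant_ids}).to_csv(
                gdir / "top_snps.tsv", sep="\t", index=False
            )
            record(gdir / "top_snps.tsv")

            cvres = cross_validate_pipeline(
                g,
                phen,
                plan,
                criterion_kind=crit.kind,
                covariates=list(config.covariates),
                screen_covariates=list(config.screen_covariates),
            )
            (gdir / "cv_result.json").write_text(
                json.dumps(
                    {
                        "fold_aucs": cvres.fold_aucs,
                        "mean_auc": cvres.mean_auc,
                        "sd_auc": cvres.sd_auc,
                        "selections": cvres.selections,
                    }
                )
            )
            record(gdir / "cv_result.json")
            best_fold = int(np.argmax(cvres.fold_aucs))
            best = cvres.models[best_fold]
            (gdir / "best_model.json").write_text(json.dumps(model_to_dict(best)))
            record(gdir / "best_model.json")
            per_group[label] = {"g": g, "phen": phen, "cv": cvres, "best": best, "top": top}
        manifest["stages"].append("per_group")

        labels = list(per_group)
        if len(labels) >= 2:
            rep = overlap_between_groups([per_group[l]["top"] for l in labels])
            overlap_out = {
                "between": {f"{a}|{b}": c for (a, b), c in rep.pairwise_proportions.items()},
                "allway": rep.allway_proportion,
            }
            first = labels[0]
            try:
                wrep = within_group_overlap(
                    per_group[first]["g"],
                    per_group[first]["phen"],
                    crit,
                    n_splits=int(config.screening.get("within_splits", 3)),
                    seed=config.seed,
                    covariates=list(config.screen_covariates),
                )
                overlap_out["within"] = {"group": first, "mean_pairwise": wrep.mean_pairwise_proportion}
            except ValueError as exc:
                overlap_out["within"] = {"group": first, "skipped": str(exc)}
            (out / "overlap.json").write_text(json.dumps(overlap_out))
            record(out / "overlap.json")

            rows = []
            for src in labels:
                for dst in labels:
                    if src == dst:
                        continue
                    res = external_validate(
                        per_group[src]["best"], per_group[dst]["g"], per_group[dst]["phen"]
                    )
                    rows.append(
                        {
                            "model": src,
                            "target": dst,
                            "auc": res.auc,
                            "n_modeled": res.n_modeled,
                            "n_matched": res.n_matched,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "external_validation.tsv", sep="\t", index=False)
            record(out / "external_validation.tsv")
        manifest["stages"].append("cross_group")

        for label in labels:
            sel = per_group[label]["cv"].selections[int(np.argmax(per_group[label]["cv"].fold_aucs))]
            spec = {
                "p": sel["p"],
                "penalty": sel["penalty"],
                "lambda": sel["lambda"],
                "criterion": crit.kind,
            }
            report = variable_contributions(
                per_group[label]["g"],
                per_group[label]["phen"],
                spec,
                seed=config.seed,
                covariates=tuple(config.covariates),
                screen_covariates=tuple(config.screen_covariates),
                mode=config.decomposition.get("mode", "out_of_fold"),
            )
            report.to_frame().to_csv(out / f"deviance_{label}.tsv", sep="\t", index=False)
            record(out / f"deviance_{label}.tsv")
        manifest["stages"].append("decomposition")
    except Exception as exc:
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
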