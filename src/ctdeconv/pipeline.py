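"""Pipeline orchestration: configuration, stage sequencing, artifacts.

A run is described by a YAML/dict configuration with explicit stage toggles.
When no input paths are given the synthetic cohort generator supplies the
data, which makes an end-to-end run fully reproducible from the global seed
alone. Every artifact directory receives a config snapshot and a JSON stamp
with the config hash, package version, and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import differential_abundance_all
from .deconv import deconvolve, run_insilico_validation
from .expression import preranked_gsea, proportion_pca, run_de_models
from .io import (
    read_bulk,
    read_cell_metadata,
    read_gmt,
    read_sample_metadata,
    read_single_cell,
    write_bulk,
    write_json,
    write_metadata,
    write_single_cell,
)
from .mediation import MediationSpec, bootstrap_mediation
from .preprocess import QCThresholds, lognormalize, qc_filter
from .signature import build_signature, one_vs_rest_markers, type_profiles
from .simulate import SimConfig, simulate_bulk_cohort, simulate_single_cell, type_mean_profiles

log = logging.getLogger("ctdeconv")

_KNOWN_KEYS = {
    "seed",
    "output_dir",
    "log_level",
    "stages",
    "paths",
    "simulation",
    "qc",
    "signature",
    "deconvolution",
    "abundance",
    "expression",
    "gsea",
    "mediation",
    "validation",
}
_STAGE_NAMES = (
    "simulate",
    "qc",
    "signature",
    "validate",
    "deconvolve",
    "abundance",
    "de",
    "gsea",
    "mediate",
)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "ctdeconv_run"
    log_level: str = "INFO"
    stages: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    signature: dict = field(default_factory=dict)
    deconvolution: dict = field(default_factory=dict)
    abundance: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    gsea: dict = field(default_factory=dict)
    mediation: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad_stage = set(cfg.stages) - set(_STAGE_NAMES)
        if bad_stage:
            raise ValueError(f"unknown stage toggles: {sorted(bad_stage)}")
        for key, p in cfg.paths.items():
            if not Path(p).exists():
                raise ValueError(f"configured path {key} = {p!r} does not exist")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order; return the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    stamp = {
        "config_hash": config.digest(),
        "package_version": __version__,
        "seed": int(config.seed),
    }
    try:
        (out / "config_snapshot.yaml").write_text(yaml.safe_dump(config.to_dict()))

        sim_cfg = SimConfig(**{"seed": config.seed, **config.simulation})
        synthetic = "sc_matrix" not in config.paths

        # --- single-cell data -------------------------------------------
        if config.enabled("simulate") and synthetic:
            log.info("simulating single-cell data (seed=%s)", config.seed)
            counts, cell_meta, _ = simulate_single_cell(sim_cfg)
            write_single_cell(counts, out / "single_cell")
            write_metadata(cell_meta, out / "single_cell" / "cell_metadata.csv")
        elif not synthetic:
            counts = read_single_cell(
                config.paths["sc_matrix"],
                config.paths["sc_features"],
                config.paths["sc_barcodes"],
            )
            cell_meta = read_cell_metadata(config.paths["cell_metadata"])
        else:
            raise ValueError("simulate stage disabled and no single-cell paths given")

        if config.enabled("qc"):
            th = QCThresholds(**config.qc)
            counts, cell_meta, qc_report = qc_filter(counts, cell_meta, th)
            write_json(qc_report, out / "qc_report.json")
            log.info("QC kept %s cells", qc_report["n_kept"])

        # --- signature ----------------------------------------------------
        sig_kwargs = {
            "g_floor": config.signature.get("g_floor", 300),
            "g_ceiling": config.signature.get("g_ceiling", 500),
            "de_q_cutoff": config.signature.get("de_q_cutoff", 0.01),
        }
        sig = None
        if config.enabled("signature"):
            norm = lognormalize(counts)
            labels = cell_meta["cell_type"]
            markers = one_vs_rest_markers(norm, labels)
            markers.to_csv(out / "markers.tsv", sep="\t", index=False)
            profiles = type_profiles(norm, labels)
            sig = build_signature(profiles, markers, **sig_kwargs)
            sig.matrix.rename_axis(index="gene").to_csv(out / "signature.tsv", sep="\t")
            write_json(
                {
                    "chosen_g": sig.chosen_g,
                    "kappa": sig.kappa,
                    **sig_kwargs,
                    **stamp,
                },
                out / "signature_meta.json",
            )
            log.info("signature: %s genes, kappa=%.3f", len(sig.genes), sig.kappa)

        # --- in silico validation ----------------------------------------
        if config.enabled("validate"):
            scenario = config.validation.get("scenario", "all")
            report = run_insilico_validation(
                counts,
                cell_meta,
                scenario=scenario,
                seed=config.seed,
                method=config.deconvolution.get("method", "nnls"),
                **sig_kwargs,
            )
            write_json(
                {
                    "scenario": scenario,
                    "pearson_r": report.pearson_r,
                    "ci95": list(report.ci95),
                    "rmse": report.rmse,
                    "n_cells": report.n_cells,
                    **stamp,
                },
                out / "validation.json",
            )
            log.info("validation %s: r=%.3f rmse=%.4f", scenario, report.pearson_r, report.rmse)

        # --- bulk cohort --------------------------------------------------
        truth = None
        if "bulk_matrix" in config.paths:
            bulk = read_bulk(
                config.paths["bulk_matrix"],
                scale=config.deconvolution.get("bulk_scale", "linear"),
            )
            sample_meta = read_sample_metadata(config.paths["sample_metadata"])
        else:
            profiles_true = type_mean_profiles(sim_cfg)
            bulk, sample_meta, truth = simulate_bulk_cohort(sim_cfg, profiles_true)
            write_bulk(bulk, out / "bulk_expression.tsv")
            write_metadata(sample_meta, out / "sample_metadata.csv")
            write_json(
                {
                    "true_por": truth.true_por.to_dict(),
                    "n_direct_effect_genes": int((truth.true_direct_log2fc != 0).sum()),
                    **stamp,
                },
                out / "sim_truth.json",
            )
            truth.true_proportions.to_csv(out / "true_proportions.tsv", sep="\t")

        props = None
        if config.enabled("deconvolve"):
            if sig is None:
                raise ValueError("deconvolve stage requires the signature stage")
            props = deconvolve(
                bulk,
                sig,
                method=config.deconvolution.get("method", "nnls"),
                n_permutations=config.deconvolution.get("n_permutations", 50),
                seed=config.seed,
            )
            combined = props.proportions.join(props.fit_stats)
            combined.rename_axis(index="sample_id").to_csv(out / "proportions.tsv", sep="\t")
            log.info("deconvolved %s samples (%s)", len(combined), props.method)

        if config.enabled("abundance"):
            source = props.proportions if props is not None else (
                truth.true_proportions if truth is not None else None
            )
            if source is None:
                raise ValueError("abundance stage needs proportions (deconvolve or synthetic truth)")
            results, report = differential_abundance_all(source, sample_meta)
            results.to_csv(out / "abundance.tsv", sep="\t")
            write_json(report, out / "abundance_report.json")
            log.info("abundance: %s types modeled, %s dropped", len(results), report["n_dropped_types"])

        def _pcs_for(source: pd.DataFrame):
            # exactly five PCs at full scale; clamped to the available rank
            # on small cohorts
            want = config.expression.get("n_pcs", 5)
            n_pcs = min(want, source.shape[1] - 1, source.shape[0] - 1)
            return proportion_pca(source, n_pcs=n_pcs)

        de_tables = None
        if config.enabled("de"):
            source = props.proportions if props is not None else truth.true_proportions
            pcs = _pcs_for(source)
            expr = bulk.matrix if bulk.scale == "log2" else np.log2(bulk.matrix + 1.0)
            de_tables, de_summary = run_de_models(
                expr,
                sample_meta,
                pcs,
                fc_cutoff=config.expression.get("fc_cutoff", 0.1),
                q_cutoff=config.expression.get("q_cutoff", 0.05),
            )
            for name, table in de_tables.items():
                table.rename_axis(index="gene").to_csv(out / f"de_{name}.tsv", sep="\t")
            write_json({**de_summary, **stamp}, out / "de_summary.json")
            log.info(
                "DE: base %s significant, adjusted %s",
                de_summary["base"]["n_significant"],
                de_summary["celltype_adjusted"]["n_significant"],
            )

        if config.enabled("gsea") and "gene_sets" in config.paths:
            if de_tables is None:
                raise ValueError("gsea stage requires the de stage")
            sets = read_gmt(config.paths["gene_sets"])
            ranked = de_tables["base"]["t_mod"]
            gsea = preranked_gsea(
                ranked,
                sets,
                n_permutations=config.gsea.get("n_permutations", 1000),
                seed=config.seed,
            )
            gsea.to_csv(out / "gsea.tsv", sep="\t")

        if config.enabled("mediate"):
            source = props.proportions if props is not None else truth.true_proportions
            pcs = _pcs_for(source)
            genes = config.mediation.get("genes")
            if genes is None and truth is not None:
                genes = [g for g, v in truth.true_direct_log2fc.items() if v != 0][:1]
            if not genes:
                raise ValueError("mediation stage needs target genes")
            expr = bulk.matrix if bulk.scale == "log2" else np.log2(bulk.matrix + 1.0)
            data = pd.concat(
                [sample_meta, pcs.scores, expr.loc[list(genes)].T], axis=1
            )
            results = {}
            for gene in genes:
                spec = MediationSpec(
                    exposure="case",
                    outcome=gene,
                    mediators=tuple(pcs.scores.columns),
                    baseline_covariates=("fetal_sex", "study"),
                    post_exposure_confounder="gestational_age",
                    interaction=config.mediation.get("interaction", False),
                    n_mc_draws=config.mediation.get("n_mc_draws", 200),
                    n_boot=config.mediation.get("n_boot", 1000),
                    seed=int(config.seed),
                )
                est = bootstrap_mediation(data, spec)
                results[gene] = {
                    "r_te": est.r_te,
                    "r_nde": est.r_nde,
                    "r_nie": est.r_nie,
                    "pm": est.pm,
                    "pm_defined": est.pm_defined,
                    "pai": est.pai,
                    "ci": {k: list(v) for k, v in est.ci.items()},
                    "n_boot": est.n_boot,
                    "n_mc_draws": spec.n_mc_draws,
                }
                log.info("mediation %s: te=%.3f pm=%.3f", gene, est.r_te, est.pm)
            write_json({**results, **{"_meta": stamp}}, out / "mediation.json")

        write_json({**stamp, "status": "complete"}, out / "run_stamp.json")
    except Exception as exc:
        write_json({**stamp, "status": "incomplete", "error": str(exc)}, out / "run_stamp.json")
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    return out
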