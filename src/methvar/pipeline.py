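"""End-to-end pipeline: QC -> association -> empirical-null adjustment ->
meta-analysis -> regions -> enrichment/covariance, per stratum.

Configuration is a YAML/dict structure (see ``DEFAULT_CONFIG``); every
output file carries the package version, config hash and seed in its
header. A manifest JSON records sample/probe counts at each stage so
conservation can be audited. A failing stage aborts with the stage name;
outputs written before the failure are left on disk.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, qc, association, empirical_null, meta as meta_mod
from . import regions as regions_mod
from . import downstream

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "cohorts": [],          # entries: name, beta, samplesheet, [detp, intensity]
    "annotation": None,
    "out_dir": "methvar_out",
    "covariates": {"numeric": ["horvath_age", "smoking_score"],
                   "categorical": ["predicted_sex", "sentrix_id",
                                   "sentrix_position"]},
    "tests": ["levene", "bartlett", "fligner_killeen"],
    "levene_center": "median",
    "variance_test": "levene",
    "adjustment": {"n_iter": 5000, "burnin": 2000},
    "alpha": 0.05,
    "regions": {},          # RegionParams overrides
    "enrichment": {},       # optional: gene_sets (gmt), expression (tsv)
    "covariance": {},       # optional: catalog (tsv), min_probes
    "strata": ["all"],      # all | male_only | female_only
    "seed": 0,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    config = {**DEFAULT_CONFIG, **user}
    for key in ("covariates", "adjustment"):
        config[key] = {**DEFAULT_CONFIG[key], **(config.get(key) or {})}
    if not config["cohorts"]:
        raise ValueError("config lists no cohorts")
    valid_strata = {"all", "male_only", "female_only"}
    unknown = set(config["strata"]) - valid_strata
    if unknown:
        raise ValueError(f"unknown stratum {sorted(unknown)[0]!r}; valid: "
                         f"{sorted(valid_strata)}")
    return config


def _subset_stratum(samplesheet: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return samplesheet
    if stratum == "male_only":
        return samplesheet[samplesheet["predicted_sex"] == "male"]
    if stratum == "female_only":
        return samplesheet[samplesheet["predicted_sex"] == "female"]
    raise ValueError(f"unknown stratum {stratum!r}")


def _covariate_spec(config: dict, stratum: str) -> association.CovariateSpec:
    cov = config["covariates"]
    categorical = list(cov["categorical"])
    if stratum in ("male_only", "female_only") and "predicted_sex" in categorical:
        categorical.remove("predicted_sex")  # single level within stratum
    return association.CovariateSpec(numeric=tuple(cov["numeric"]),
                                     categorical=tuple(categorical))


def run_pipeline(config) -> dict:
    """Execute all configured strata; returns the manifest dict."""
    config = load_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    manifest: dict = {"version": __version__, "seed": seed,
                      "config_hash": io.config_hash(config), "strata": {}}

    stage = "load_inputs"
    try:
        annotation = (io.read_annotation(config["annotation"])
                      if config["annotation"] else None)
        cohort_data = {}
        for entry in config["cohorts"]:
            name = entry["name"]
            cohort_data[name] = {
                "beta": io.read_beta_matrix(entry["beta"]),
                "detp": (io.read_detection_p(entry["detp"])
                         if entry.get("detp") else None),
                "intensity": (pd.read_csv(entry["intensity"], comment="#",
                                          index_col="sample_id")
                              if entry.get("intensity") else None),
                "samplesheet": io.read_samplesheet(entry["samplesheet"]),
            }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    for stratum in config["strata"]:
        manifest["strata"][stratum] = _run_stratum(
            config, cohort_data, annotation, out_dir / stratum, stratum)

    stage = "manifest"
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_stratum(config: dict, cohort_data: dict, annotation, out_dir: Path,
                 stratum: str) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    counts: dict = {"cohorts": {}}
    spec = _covariate_spec(config, stratum)
    adjusted_stats: dict[str, pd.DataFrame] = {}

    for name, data in cohort_data.items():
        stage = f"qc[{name}]"
        try:
            sheet = _subset_stratum(data["samplesheet"], stratum)
            beta = data["beta"][data["beta"].columns.intersection(sheet.index)]
            detp = (data["detp"][beta.columns]
                    if data["detp"] is not None else None)
            intensity = (data["intensity"].loc[beta.columns]
                         if data["intensity"] is not None else None)
            kept_samples, sample_report = qc.filter_samples(
                beta, detp, intensity, sheet)
            beta = beta[kept_samples]
            detp = detp[kept_samples] if detp is not None else None
            if annotation is not None:
                kept_probes, probe_report = qc.filter_probes(
                    beta, detp, annotation)
                beta = beta.loc[kept_probes]
            else:
                probe_report = None
            sample_report.table.to_csv(out_dir / f"{name}_sample_qc.tsv",
                                       sep="\t")
            if probe_report is not None:
                probe_report.table.to_csv(out_dir / f"{name}_probe_qc.tsv",
                                          sep="\t")
            counts["cohorts"][name] = {
                "n_samples_in": sample_report.n_before,
                "n_samples_kept": sample_report.n_after,
                "n_probes_in": (probe_report.n_before if probe_report
                                else len(beta)),
                "n_probes_kept": len(beta),
            }
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = f"association[{name}]"
        try:
            stats_df = association.run_cohort_association(
                beta, sheet.loc[beta.columns], spec,
                tests=tuple(config["tests"]),
                levene_center=config["levene_center"])
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = f"adjust[{name}]"
        try:
            settings = empirical_null.NullSettings(
                n_iter=config["adjustment"]["n_iter"],
                burnin=config["adjustment"]["burnin"], seed=seed)
            stats_adj, estimates = empirical_null.adjust_cohort_stats(
                stats_df, tests=tuple(config["tests"]), settings=settings)
            io.write_summary_stats(stats_adj, out_dir / f"{name}_stats.tsv",
                                   seed=seed, config=config)
            with open(out_dir / f"{name}_null_estimates.json", "w") as fh:
                json.dump({k: v.to_dict() for k, v in estimates.items()},
                          fh, indent=2)
            adjusted_stats[name] = stats_adj
            counts["cohorts"][name]["n_probes_stats"] = len(stats_adj)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    stage = "meta"
    try:
        meta_table = meta_mod.meta_analyse(
            adjusted_stats, variance_test=config["variance_test"],
            alpha=config["alpha"])
        meta_table, summary = meta_mod.classify(meta_table,
                                                alpha=config["alpha"])
        io.write_summary_stats(meta_table, out_dir / "meta.tsv",
                               seed=seed, config=config)
        counts["meta"] = {
            "n_probes": len(meta_table),
            "m_tests": meta_table.attrs["m_tests"],
            "bonferroni_threshold": meta_table.attrs["bonferroni_threshold"],
            **summary.to_dict(),
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    if annotation is not None:
        stage = "regions"
        try:
            params = regions_mod.RegionParams(**(config["regions"] or {}))
            region_table = regions_mod.find_regions(meta_table, annotation,
                                                    params)
            region_table.to_csv(out_dir / "regions.tsv", sep="\t", index=False)
            if len(region_table):
                io.write_bed(region_table[["chrom", "start", "end",
                                           "n_probes"]],
                             out_dir / "regions.bed", seed=seed)
            counts["regions"] = {"n_regions": len(region_table)}
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    enrich_cfg = config.get("enrichment") or {}
    if enrich_cfg.get("gene_sets") and annotation is not None:
        stage = "enrichment"
        try:
            sets = io.read_gmt(enrich_cfg["gene_sets"])
            hits = meta_table.index[meta_table["fdr_significant"]]
            hit_genes = downstream.probes_to_genes(hits, annotation)
            universe = downstream.probes_to_genes(meta_table.index, annotation)
            result = downstream.fisher_enrichment(hit_genes, universe, sets)
            result.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
            counts["enrichment"] = {"n_sets": len(sets)}
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    cov_cfg = config.get("covariance") or {}
    if cov_cfg.get("catalog"):
        stage = "covariance"
        try:
            catalog = pd.read_csv(cov_cfg["catalog"], sep="\t", comment="#")
            result = downstream.epigenetic_covariance(
                meta_table["z_meta"], catalog,
                min_probes=cov_cfg.get("min_probes",
                                       downstream.MIN_CATALOG_PROBES))
            result.to_csv(out_dir / "covariance.tsv", sep="\t", index=False)
            counts["covariance"] = {"n_traits": len(result)}
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    return counts
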