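"""End-to-end orchestration: prep -> fit -> composition -> geometry ->
join -> stats.

The pipeline consumes either a synthetic-cohort block or a directory of
per-gene FASTA alignments plus a Newick topology and annotation/covariate
tables, and produces the per-gene covariate table joining dS, dN, dN/dS
with distance-to-IR, substitution tolerance, GC3 and expression, followed
by the full statistical battery (group contrasts, fold differences, simple
regressions, all-subsets search and LMG relative importance).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (alignment_prep, codon_model, composition, constraint_stats,
               genome_geometry, io_formats, synthetic_data)
from .errors import ConfigError, DataError, PlastidRatesError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("plastidrates")

STAGES = ("prep", "fit", "composition", "geometry", "join", "stats")

#: responses analysed and the contrast test used for each (the dS contrast
#: uses Welch's t, dN and dN/dS use the Wilcoxon rank-sum test)
RESPONSE_TESTS = {"dS": "welch_t", "dN": "wilcoxon", "dn_ds": "wilcoxon"}


class PipelineError(PlastidRatesError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Run configuration; fully serialisable to/from TOML."""

    output_dir: str = "plastidrates_out"
    seed: int = 0
    synthetic: synthetic_data.SyntheticConfig | None = None
    input_dir: str | None = None
    trim_max_gap_fraction: float = 0.9
    genetic_code: int = 1
    ir_min_length: int = 1000
    log_mrna: bool = True          # log10-transform mRNA abundance
    predictors: tuple[str, ...] = ("mean_distance", "tolerance_score",
                                   "gc3_mean", "mrna")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        if syn is not None:
            if "codons_per_gene" in syn and isinstance(
                    syn["codons_per_gene"], list):
                syn["codons_per_gene"] = tuple(syn["codons_per_gene"])
            if "omega_range" in syn:
                syn["omega_range"] = tuple(syn["omega_range"])
            if "freq_base" in syn:
                syn["freq_base"] = tuple(syn["freq_base"])
            cfg.synthetic = synthetic_data.SyntheticConfig(**syn)
        return cfg

    def as_dict(self) -> dict:
        out = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "input_dir": self.input_dir,
            "trim_max_gap_fraction": self.trim_max_gap_fraction,
            "genetic_code": self.genetic_code,
            "ir_min_length": self.ir_min_length,
            "log_mrna": self.log_mrna,
            "predictors": list(self.predictors),
        }
        if self.synthetic is not None:
            out["synthetic"] = self.synthetic.as_dict()
        return out


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_prep(config: PipelineConfig):
    if config.synthetic is not None:
        syn = config.synthetic
        if syn.seed != config.seed:
            syn = synthetic_data.SyntheticConfig(
                **{**syn.as_dict(), "seed": config.seed,
                   "codons_per_gene": tuple(syn.codons_list()),
                   "omega_range": tuple(syn.omega_range),
                   "freq_base": tuple(syn.freq_base)})
        cohort = synthetic_data.generate_cohort(syn)
        alignments = cohort.alignments
        tree = cohort.tree
        layouts = cohort.layout_set.layouts
        covariates = cohort.covariates
    elif config.input_dir is not None:
        indir = Path(config.input_dir)
        if not indir.is_dir():
            raise DataError(f"input directory {indir} does not exist")
        tree = io_formats.read_newick(indir / "tree.nwk")
        layouts = io_formats.read_annotations(indir / "layouts.tsv")
        covariates = pd.read_csv(indir / "covariates.tsv", sep="\t")
        alignments = {}
        fasta_files = sorted(indir.glob("*.fasta"))
        if not fasta_files:
            raise DataError(f"no per-gene FASTA files in {indir}")
        for f in fasta_files:
            gid = f.stem
            alignments[gid] = alignment_prep.CodonAlignment(
                gene_id=gid, sequences=io_formats.read_fasta(f),
                genetic_code=config.genetic_code)
    else:
        raise ConfigError("config needs a synthetic block or an input_dir")

    trimmed = {}
    trim_rows = []
    for gid, aln in alignments.items():
        t, removed = alignment_prep.trim_gap_columns(
            aln, config.trim_max_gap_fraction)
        trimmed[gid] = t
        trim_rows += [(gid, col, frac) for col, frac in removed]
    trim_report = pd.DataFrame(trim_rows,
                               columns=["gene", "column", "gap_fraction"])
    return trimmed, tree, layouts, covariates, trim_report


def _stage_fit(alignments, tree, genetic_code) -> tuple[pd.DataFrame, list]:
    fits = []
    rows = []
    for gid in sorted(alignments):
        fit = codon_model.fit_gene(alignments[gid], tree,
                                   genetic_code=genetic_code)
        fits.append(fit)
        rows.append((gid, fit.dS, fit.dN, fit.dn_ds, fit.omega,
                     fit.log_likelihood, len(fit.branch_table),
                     fit.max_branch_dS, fit.max_branch_dN))
    table = pd.DataFrame(rows, columns=[
        "gene", "dS", "dN", "dn_ds", "omega", "logL", "n_branches",
        "max_branch_dS", "max_branch_dN"])
    return table, fits


def _stage_stats(table: pd.DataFrame, config: PipelineConfig) -> dict:
    out: dict[str, object] = {}
    mrna_col = "log10_mrna" if config.log_mrna else "mrna_abundance"

    contrasts = []
    for resp, test in RESPONSE_TESTS.items():
        groups = {cat: sub[resp].to_numpy()
                  for cat, sub in table.groupby("category")}
        if len(groups) == 2 and all(len(v) >= 2 for v in groups.values()):
            c = constraint_stats.group_contrast(groups, test=test)
            contrasts.append((resp, test, c.statistic, c.p_value,
                              c.fold_difference, c.larger_group))
    out["contrasts"] = pd.DataFrame(contrasts, columns=[
        "response", "test", "statistic", "p_value", "fold_difference",
        "larger_group"])

    folds = []
    for resp in RESPONSE_TESTS:
        ratio, hi, lo = constraint_stats.fold_difference(
            table.set_index("gene")[resp])
        folds.append((resp, ratio, hi, lo))
    out["fold_differences"] = pd.DataFrame(
        folds, columns=["response", "fold", "fastest_gene", "slowest_gene"])

    predictors = [mrna_col if p == "mrna" else p for p in config.predictors]
    regressions = []
    for resp in RESPONSE_TESTS:
        for pred in predictors:
            sub = table[[resp, pred]].dropna()
            r = constraint_stats.simple_regression(sub[resp], sub[pred])
            regressions.append((resp, pred, r.slope, r.intercept,
                                r.r_squared, r.p_value, r.n))
    out["regressions"] = pd.DataFrame(regressions, columns=[
        "response", "predictor", "slope", "intercept", "r_squared",
        "p_value", "n"])

    subset_rows = []
    importance_rows = []
    for resp in RESPONSE_TESTS:
        sub = table[[resp] + predictors].dropna()
        if len(sub) <= len(predictors) + 2:
            logger.warning(
                "skipping all-subsets/LMG for %s: only %d complete rows "
                "for %d predictors", resp, len(sub), len(predictors))
            continue
        res = constraint_stats.all_subsets(sub[resp], sub[predictors])
        subset_rows.append((resp, "|".join(res.best_subset), res.best_r2,
                            res.best_adj_r2, len(res.table)))
        best = list(res.best_subset)
        imp = constraint_stats.lmg_importance(sub[resp], sub[best],
                                              response_name=resp)
        for pred in best:
            importance_rows.append((resp, pred, imp.full_r2,
                                    imp.shares[pred],
                                    imp.percentages[pred]))
    out["best_subsets"] = pd.DataFrame(subset_rows, columns=[
        "response", "best_subset", "r2", "adj_r2", "n_models"])
    out["relative_importance"] = pd.DataFrame(importance_rows, columns=[
        "response", "predictor", "full_r2", "lmg_share", "lmg_percent"])

    numeric = table[["dS", "dN", "dn_ds"] + predictors]
    out["correlations"] = constraint_stats.correlation_matrix(numeric)
    return out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest.

    Output tables are written to ``config.output_dir`` as TSV.  A stage
    failure raises :class:`PipelineError` naming the stage; outputs of
    earlier stages remain on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "package_version": __import__("plastidrates").__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "completed_stages": [],
        "row_counts": {},
        "log_mrna": config.log_mrna,
    }
    io_formats.dump_toml(config.as_dict(), outdir / "config_echo.toml")

    def run_stage(name, fn, *args):
        logger.info("stage %s", name)
        try:
            result = fn(*args)
        except PlastidRatesError as exc:
            raise PipelineError(name, exc) from exc
        manifest["completed_stages"].append(name)
        return result

    trimmed, tree, layouts, covariates, trim_report = run_stage(
        "prep", _stage_prep, config)
    trim_report.to_csv(outdir / "trim_report.tsv", sep="\t", index=False)
    io_formats.write_newick(tree, outdir / "topology.nwk")
    manifest["row_counts"]["genes"] = len(trimmed)

    fit_table, fits = run_stage("fit", _stage_fit, trimmed, tree,
                                config.genetic_code)
    fit_table.to_csv(outdir / "gene_fits.tsv", sep="\t", index=False)
    branch_tables = pd.concat(
        [f.branch_table.assign(gene=f.gene_id) for f in fits],
        ignore_index=True)[["gene", "edge_id", "length", "dS", "dN"]]
    branch_tables.to_csv(outdir / "branch_fits.tsv", sep="\t", index=False)
    sat = codon_model.saturation_report(fits)
    sat.to_csv(outdir / "saturation.tsv", sep="\t", index=False)
    manifest["row_counts"]["fits"] = len(fit_table)
    manifest["max_branch_dS"] = sat.attrs["max_dS"]
    manifest["max_branch_dN"] = sat.attrs["max_dN"]

    comp_table = run_stage(
        "composition", composition.composition_table,
        [trimmed[g] for g in sorted(trimmed)])
    comp_table.to_csv(outdir / "composition.tsv", sep="\t", index=False)

    dist_table = run_stage("geometry", genome_geometry.average_gene_distance,
                           layouts)
    dist_table.to_csv(outdir / "gene_distance.tsv", sep="\t", index=False)
    dist_table.attrs["per_species"].to_csv(
        outdir / "gene_distance_per_species.tsv", sep="\t", index=False)

    def _join():
        t = (fit_table.merge(dist_table, on="gene", validate="1:1")
             .merge(comp_table, on="gene", validate="1:1")
             .merge(covariates, on="gene", how="left", validate="1:1"))
        if "mrna_abundance" in t.columns:
            t["log10_mrna"] = np.log10(t["mrna_abundance"])
        return t

    covariate_table = run_stage("join", _join)
    covariate_table.to_csv(outdir / "gene_covariates.tsv", sep="\t",
                           index=False)
    manifest["row_counts"]["covariate_table"] = len(covariate_table)

    stats = run_stage("stats", _stage_stats, covariate_table, config)
    for name, df in stats.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t",
                  index=(name == "correlations"))
    manifest["row_counts"]["regressions"] = len(stats["regressions"])

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
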