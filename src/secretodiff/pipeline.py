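"""End-to-end orchestration of the differential-secretion analysis.

Stage order: per-batch QC filtering, sample exclusions, log2 transform
and replicate-presence filter; batch merge; GOCC secreted-protein
restriction; per-sample median centering; condition-aware down-shifted
imputation; Welch/BH differential testing with hit calling; hierarchical
clustering of the z-scored matrix.  All randomness flows from one
top-level seed.
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

from . import io as io_mod
from .clustering import HierarchicalClusterer
from .containers import (DEFAULT_SECRETED_TERMS, FilterReport, GoccAnnotation,
                         LogIntensityMatrix, StudyDesign)
from .differential import (WelchDifferentialTester, log2fc_heatmap_table,
                           overlap_summary)
from .imputation import ImputationParams, impute
from .io import ProteinTable
from .preprocess import (SecretedFilter, median_center, merge_batches,
                         preprocess_batch)
from .simulate import SimulatedDataset, SimulationSpec, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline settings; defaults reproduce the reference analysis
    (tau 0.5, six secreted GOCC terms, shifts 0.5/1.8 SD, width 0.3 SD,
    FDR < 0.1, |log2FC| >= 1)."""

    protein_groups: dict = field(default_factory=dict)  # batch -> path
    design_path: str | None = None
    gocc_path: str | None = None
    exclusions: list = field(default_factory=list)      # [(donor, condition), ...]
    untreated_label: str = "UT"
    tau: float = 0.5
    secreted_terms: tuple = DEFAULT_SECRETED_TERMS
    imputation: ImputationParams = field(default_factory=ImputationParams)
    fdr_cut: float = 0.1
    lfc_cut: float = 1.0
    family: str = "per_contrast"
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.tau <= 1):
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if not self.secreted_terms:
            raise ValueError("secreted_terms must be non-empty")
        if isinstance(self.imputation, dict):
            self.imputation = ImputationParams(**self.imputation)
        # stage seeds derive deterministically from the top-level seed
        if self.imputation.seed == 0 and self.seed != 0:
            self.imputation = dataclasses.replace(
                self.imputation, seed=derive_seed(self.seed, "imputation"))

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["secreted_terms"] = list(self.secreted_terms)
        d["exclusions"] = [list(e) for e in self.exclusions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "secreted_terms" in d:
            d["secreted_terms"] = tuple(d["secreted_terms"])
        if "exclusions" in d:
            d["exclusions"] = [tuple(e) for e in d["exclusions"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunResult:
    report: FilterReport
    results: pd.DataFrame
    matrix: LogIntensityMatrix        # imputed
    clusterer: HierarchicalClusterer
    overlap: pd.DataFrame
    manifest: dict


def run_tables(
    tables: dict[str, ProteinTable],
    design: StudyDesign,
    gocc: GoccAnnotation,
    config: RunConfig,
    cluster: bool = True,
) -> RunResult:
    """Run the pipeline on in-memory tables (core of :func:`run`)."""
    design.validate_contrasts()
    report = FilterReport()

    # per-batch: QC -> exclusions -> log2 -> presence filter
    per_batch = {}
    for batch, table in tables.items():
        logger.info("batch %s: %d input rows", batch, len(table))
        per_batch[batch] = preprocess_batch(table, design, batch,
                                            tau=config.tau, report=report)
        # embedded GOCC columns supplement the external annotation table
        gocc = table.gocc_annotation().merged_with(gocc)

    batches = list(per_batch)
    merged = per_batch[batches[0]]
    for b in batches[1:]:
        merged = merge_batches(merged, per_batch[b])

    sec = SecretedFilter(gocc, tuple(config.secreted_terms))
    restricted = sec.fit_transform(merged)
    kept = set(restricted.protein_ids)
    for batch in batches:
        batch_prots = per_batch[batch].protein_ids
        n_drop = sum(p not in kept for p in batch_prots)
        report.record(batch, non_secreted=n_drop, retained=-n_drop)
    report.assert_conserving()

    centered = median_center(restricted)
    imputed, audit = impute(centered, design, config.imputation)

    tester = WelchDifferentialTester(design, config.fdr_cut, config.lfc_cut,
                                     config.family).fit(imputed)
    results = tester.results_
    overlap = overlap_summary(results)

    clusterer = HierarchicalClusterer(config.cluster_metric, config.cluster_method)
    if cluster:
        clusterer.fit(imputed)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_proteins_analyzed": len(imputed.protein_ids),
        "n_samples": len(imputed.sample_ids),
        "n_imputed_cells": int(sum(r["n_imputed"] for r in audit.records)),
        "n_hits": int(results["hit"].sum()),
    }
    return RunResult(report, results, imputed, clusterer, overlap, manifest)


def run(config: RunConfig, dry_run: bool = False) -> RunResult | None:
    """File-based entry point: read inputs, run, optionally write outputs."""
    design = io_mod.read_design(config.design_path,
                                exclusions=config.exclusions,
                                untreated_label=config.untreated_label)
    tables = {batch: io_mod.read_protein_groups(path, design.subset(
                  design.table.loc[design.table["batch"] == batch, "sample_id"]))
              for batch, path in config.protein_groups.items()}
    gocc = (io_mod.read_gocc(config.gocc_path) if config.gocc_path
            else GoccAnnotation({}))
    if dry_run:
        logger.info("dry run: inputs validated")
        return None
    result = run_tables(tables, design, gocc, config)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_mod.write_results(result.results, out / "results.tsv")
        io_mod.write_matrix(result.matrix, out / "imputed_matrix.tsv")
        result.report.to_frame().to_csv(out / "filter_report.tsv", sep="\t",
                                        index=False)
        result.overlap.to_csv(out / "overlap.tsv", sep="\t", index=False)
        log2fc_heatmap_table(result.results).to_csv(out / "hit_log2fc.tsv",
                                                    sep="\t")
        result.clusterer.result_.linkage_frame("col").to_csv(
            out / "col_linkage.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=2, default=str)
        config.to_yaml(out / "config_used.yaml")
    return result


# ----------------------------------------------------------------------
# simulation-based recovery harness
# ----------------------------------------------------------------------

def run_simulated(ds: SimulatedDataset, config: RunConfig,
                  cluster: bool = False) -> RunResult:
    return run_tables(ds.tables, ds.design, ds.gocc, config, cluster=cluster)


def recover(spec: SimulationSpec, config: RunConfig | None = None,
            n_rep: int = 20, seed: int = 0) -> pd.DataFrame:
    """Score hit calling against planted truth over ``n_rep`` simulations.

    For each replicate: simulate -> full pipeline -> compare.  Reported
    per replicate: log2FC bias and RMSE over affected proteins (all, and
    the fully observed subset), recall of true effects with |delta| >= the
    hit threshold, number of hits, false positives, and empirical FDR
    (NaN when there are no hits).
    """
    rows = []
    for r in range(n_rep):
        rep_seed = derive_seed(seed, f"rep{r}")
        ds = simulate(spec, seed=rep_seed)
        cfg = config or RunConfig()
        cfg = dataclasses.replace(
            cfg, seed=rep_seed,
            imputation=dataclasses.replace(cfg.imputation,
                                           seed=derive_seed(rep_seed, "imputation")),
        )
        res = run_simulated(ds, cfg)
        rows.append(_score_replicate(ds, res, cfg))
    return pd.DataFrame(rows)


def _score_replicate(ds: SimulatedDataset, res: RunResult,
                     config: RunConfig) -> dict:
    results = res.results
    truth = ds.truth
    design = ds.design.apply_exclusions()

    biases, biases_fo, est_fo, sq_errs, n_true, n_found = [], [], [], [], 0, 0
    n_hits = int(results["hit"].sum())
    n_false = 0
    for (batch, contrast), grp in results.groupby(["batch", "contrast"]):
        treat = contrast.split("_vs_")[0]
        col = f"{batch}|{treat}"
        if col not in truth.effects.columns:
            continue
        true_eff = truth.effects[col].reindex(grp["protein_id"]).fillna(0.0)
        est = grp.set_index("protein_id")["log2fc"]
        affected = true_eff[true_eff != 0]
        # fully observed = no censored cells in this contrast's samples
        samples = (design.group_samples(batch, treat)
                   + design.group_samples(batch, design.untreated_label))
        samples = [s for s in samples if s in truth.missing_cause.columns]
        fully_obs = (truth.missing_cause[samples] == "detected").all(axis=1)
        for pid, delta in affected.items():
            if pid not in est.index:
                continue
            err = est[pid] - delta
            biases.append(err)
            sq_errs.append(err**2)
            if fully_obs.get(pid, False):
                biases_fo.append(err)
                est_fo.append(est[pid])
        truly = affected[affected.abs() >= config.lfc_cut].index
        n_true += len(truly)
        hit_ids = set(grp.loc[grp["hit"], "protein_id"])
        n_found += len(hit_ids & set(truly))
        n_false += len(hit_ids - set(affected.index))
    return {
        "bias": float(np.mean(biases)) if biases else np.nan,
        "bias_fully_observed": float(np.mean(biases_fo)) if biases_fo else np.nan,
        "n_fully_observed": len(biases_fo),
        "mean_est_fully_observed": float(np.mean(est_fo)) if est_fo else np.nan,
        "rmse": float(np.sqrt(np.mean(sq_errs))) if sq_errs else np.nan,
        "recall": n_found / n_true if n_true else np.nan,
        "n_hits": n_hits,
        "n_false_hits": n_false,
        "empirical_fdr": n_false / n_hits if n_hits else np.nan,
    }
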