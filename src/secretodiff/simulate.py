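"""Synthetic LFQ secretome data with ground truth.

The generator emulates the statistical structure of a two-batch placental
explant secretomics study: ~1400 proteins per batch quantified by LFQ in
four conditions (untreated plus three particle exposures) with 4-5
biological replicates, lognormal intensities (normal on the log2 scale),
a discrete batch offset, sparse planted treatment effects, left-censored
(intensity-dependent) missingness, decoy/contaminant/site-only rows, and
optional degenerate samples with >95% of entries unmeasured.

Every generated dataset ships with a :class:`TruthTable` so that filter,
imputation and testing stages can be scored against known ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DEFAULT_SECRETED_TERMS, GoccAnnotation, StudyDesign
from .io import ProteinTable

NONSECRETED_TERMS = ("nucleus", "cytoplasm", "mitochondrion", "plasma membrane")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the generative model (defaults = study-like design)."""

    n_proteins: int = 1400
    #: batch -> condition -> number of biological replicates
    design: dict = field(default_factory=lambda: {
        "first_trimester": {"UT": 4, "TiO2": 4, "SiO2": 4, "DEP": 4},
        "term": {"UT": 5, "TiO2": 4, "SiO2": 4, "DEP": 4},
    })
    mu0: float = 25.0          # baseline log2 intensity mean
    sd0: float = 2.0           # between-protein baseline SD
    sd_e: float = 0.5          # within-group replicate noise SD (log2)
    delta_b: float = 2.0       # additive batch offset (log2), applied to 2nd batch
    pi: float = 0.02           # fraction of secreted proteins affected per treatment
    effect_sizes: tuple = (-2.0, -1.5, 1.5, 2.0)
    miss_c: float = 22.0       # detection midpoint: P(missing)=0.5 at this log2 value
    miss_w: float = 1.0        # logistic width of the censoring curve
    frac_decoy: float = 0.02
    frac_contaminant: float = 0.02
    frac_site_only: float = 0.02
    frac_nonsecreted: float = 0.2
    #: sample ids forced to >95% missingness (built after naming, see below)
    degenerate_samples: tuple = ("term_UT_d14", "term_UT_d16")
    degenerate_rate: float = 0.97
    untreated_label: str = "UT"

    def __post_init__(self) -> None:
        if not (0 <= self.pi <= 1):
            raise ValueError("pi must be in [0, 1]")
        if min(self.sd0, self.sd_e, self.miss_w) <= 0:
            raise ValueError("sd0, sd_e and miss_w must be > 0")
        for batch, conds in self.design.items():
            for cond, n in conds.items():
                if n < 2:
                    raise ValueError(
                        f"replicate count < 2 in group ({batch}, {cond})")


@dataclass
class TruthTable:
    """Planted ground truth for one simulated dataset."""

    secreted: pd.Series                # protein_id -> bool
    effects: pd.DataFrame              # protein_id x "<batch>|<treatment>" log2FC
    missing_cause: pd.DataFrame        # protein x sample: detected/censored/forced
    baseline: pd.Series                # protein_id -> baseline log2 intensity

    def affected(self, batch: str, treatment: str) -> pd.Series:
        col = f"{batch}|{treatment}"
        return self.effects[col][self.effects[col] != 0]


@dataclass
class SimulatedDataset:
    tables: dict                       # batch -> ProteinTable
    design: StudyDesign
    gocc: GoccAnnotation
    truth: TruthTable
    log2_true: pd.DataFrame            # noise-free-missingness log2 matrix (pre-censor)


def _build_design(spec: SimulationSpec) -> StudyDesign:
    rows = []
    for batch, conds in spec.design.items():
        for cond, n in conds.items():
            # degenerate samples are named after donors 14/16 so the
            # study-style exclusion rule can target them
            donors = list(range(1, n + 1))
            names = [f"{batch}_{cond}_d{d}" for d in donors]
            forced = [s for s in spec.degenerate_samples
                      if s.startswith(f"{batch}_{cond}_")]
            for s in forced:
                if s not in names:
                    names.append(s)
                    donors.append(int(s.rsplit("_d", 1)[1]))
            for rep, (d, name) in enumerate(zip(donors, names), start=1):
                rows.append({"sample_id": name, "batch": batch, "condition": cond,
                             "donor": str(d), "replicate": rep})
    exclusions = tuple(
        (s.rsplit("_d", 1)[1], s.split("_")[-2]) for s in spec.degenerate_samples
    )
    return StudyDesign(pd.DataFrame(rows), exclusions=exclusions,
                       untreated_label=spec.untreated_label)


def simulate(spec: SimulationSpec, seed: int = 0,
             out_dir: str | Path | None = None) -> SimulatedDataset:
    """Generate one dataset; identical seed gives identical output.

    When ``out_dir`` is given, the proteinGroups-dialect TSV per batch,
    the design TSV, the GOCC TSV and the truth-effects TSV are written
    there (raw intensities rounded to 6 significant figures).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EC]))
    design = _build_design(spec)

    n = spec.n_proteins
    pids = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    secreted = np.ones(n, dtype=bool)
    n_nonsec = int(round(spec.frac_nonsecreted * n))
    secreted[rng.choice(n, size=n_nonsec, replace=False)] = False

    gocc_terms = {}
    for i, pid in enumerate(pids):
        pool = DEFAULT_SECRETED_TERMS if secreted[i] else NONSECRETED_TERMS
        gocc_terms[pid] = frozenset({pool[rng.integers(len(pool))]})
    gocc = GoccAnnotation(gocc_terms)

    baseline = rng.normal(spec.mu0, spec.sd0, size=n)
    batches = list(spec.design)
    batch_offset = {b: (spec.delta_b if j == 1 else 0.0)
                    for j, b in enumerate(batches)}

    # planted effects on secreted proteins only
    sec_idx = np.nonzero(secreted)[0]
    effects = {}
    for batch in batches:
        for treat in [c for c in spec.design[batch] if c != spec.untreated_label]:
            eff = np.zeros(n)
            n_aff = int(round(spec.pi * len(sec_idx)))
            if n_aff:
                chosen = rng.choice(sec_idx, size=n_aff, replace=False)
                eff[chosen] = rng.choice(spec.effect_sizes, size=n_aff)
            effects[f"{batch}|{treat}"] = eff
    effects_df = pd.DataFrame(effects, index=pids)

    sample_rows = design.table
    values = {}
    causes = {}
    for _, row in sample_rows.iterrows():
        s, batch, cond = row["sample_id"], row["batch"], row["condition"]
        x = baseline + batch_offset[batch]
        key = f"{batch}|{cond}"
        if key in effects_df.columns:
            x = x + effects_df[key].to_numpy()
        x = x + rng.normal(0, spec.sd_e, size=n)
        from scipy.special import expit
        p_missing = expit((spec.miss_c - x) / spec.miss_w)
        censored = rng.random(n) < p_missing
        cause = np.where(censored, "censored", "detected")
        if s in spec.degenerate_samples:
            n_forced = int(np.ceil(spec.degenerate_rate * n))
            forced = rng.choice(n, size=n_forced, replace=False)
            censored = censored.copy()
            censored[forced] = True
            cause = np.where(censored, "forced", "detected")
        values[s] = np.where(censored, np.nan, x)
        causes[s] = cause

    log2_true = pd.DataFrame(values, index=pids)
    truth = TruthTable(
        secreted=pd.Series(secreted, index=pids),
        effects=effects_df,
        missing_cause=pd.DataFrame(causes, index=pids),
        baseline=pd.Series(baseline, index=pids),
    )

    tables = {b: _protein_table_for_batch(spec, rng, b, design, log2_true,
                                          pids, gocc_terms)
              for b in batches}
    ds = SimulatedDataset(tables, design, gocc, truth, log2_true)
    if out_dir is not None:
        _write_dataset(ds, spec, Path(out_dir))
    return ds


def _round_sig(a: np.ndarray, sig: int = 6) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        mag = np.floor(np.log10(np.abs(a)))
        factor = 10.0 ** (sig - 1 - mag)
        out = np.round(a * factor) / factor
    return np.where(np.isfinite(a) & (a != 0), out, a)


def _protein_table_for_batch(spec, rng, batch, design, log2_true, pids, gocc_terms):
    samples = [s for s in design.sample_ids
               if design.table.set_index("sample_id").loc[s, "batch"] == batch]
    inten = pd.DataFrame(
        _round_sig(2.0 ** log2_true[samples].to_numpy()),
        columns=samples, index=range(len(pids)),
    )
    meta = pd.DataFrame({
        "protein_ids": pids, "protein_id": pids,
        "gene_names": [f"GENE{p[1:]}" for p in pids],
        "flag_reverse": False, "flag_contaminant": False, "flag_site_only": False,
        "gocc_terms": [gocc_terms[p] for p in pids],
    })

    # junk rows: decoys, contaminants, site-only identifications
    extra_meta, extra_rows = [], []
    specs = [("REV__Q", "flag_reverse", spec.frac_decoy),
             ("CON__C", "flag_contaminant", spec.frac_contaminant),
             ("SO__S", "flag_site_only", spec.frac_site_only)]
    k = 0
    for prefix, flag, frac in specs:
        for _ in range(int(round(frac * len(pids)))):
            k += 1
            pid = f"{prefix}{k:05d}"
            x = rng.normal(spec.mu0, spec.sd0, size=len(samples))
            # junk rows share the degenerate samples' forced dropout
            p_miss = np.array([spec.degenerate_rate
                               if s in spec.degenerate_samples else 0.5
                               for s in samples])
            miss = rng.random(len(samples)) < p_miss
            extra_rows.append(np.where(miss, np.nan,
                                       _round_sig(2.0 ** x)))
            row = {"protein_ids": pid, "protein_id": pid, "gene_names": "",
                   "flag_reverse": False, "flag_contaminant": False,
                   "flag_site_only": False, "gocc_terms": frozenset()}
            row[flag] = True
            extra_meta.append(row)
    if extra_meta:
        meta = pd.concat([meta, pd.DataFrame(extra_meta)], ignore_index=True)
        inten = pd.concat(
            [inten, pd.DataFrame(np.array(extra_rows), columns=samples)],
            ignore_index=True,
        )
    return ProteinTable(meta, inten)


def _write_dataset(ds: SimulatedDataset, spec: SimulationSpec, out_dir: Path) -> None:
    from . import io as io_mod

    out_dir.mkdir(parents=True, exist_ok=True)
    for batch, table in ds.tables.items():
        df = pd.DataFrame({
            "Protein IDs": table.meta["protein_ids"],
            "Gene names": table.meta["gene_names"],
            "Reverse": np.where(table.meta["flag_reverse"], "+", ""),
            "Potential contaminant": np.where(table.meta["flag_contaminant"], "+", ""),
            "Only identified by site": np.where(table.meta["flag_site_only"], "+", ""),
        })
        for s in table.intensities.columns:
            df[f"LFQ intensity {s}"] = table.intensities[s].fillna(0.0)
        df.to_csv(out_dir / f"proteinGroups_{batch}.txt", sep="\t", index=False)
    io_mod.write_design(ds.design, out_dir / "design.tsv")
    io_mod.write_gocc(ds.gocc, out_dir / "gocc.tsv")
    eff = ds.truth.effects.copy()
    eff.insert(0, "secreted", ds.truth.secreted)
    eff.index.name = "protein_id"
    eff.to_csv(out_dir / "truth_effects.tsv", sep="\t")


def null_spec(**overrides) -> SimulationSpec:
    """Spec with no planted effects (pi = 0)."""
    return replace(SimulationSpec(), pi=0.0, **overrides)
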