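"""Readers and writers for the external tables the pipeline touches.

The main input dialect is MaxQuant's ``proteinGroups.txt``: a tab-separated
table with one row per protein group, per-sample ``LFQ intensity <sample>``
columns, and ``+``-coded QC flag columns (``Reverse``,
``Potential contaminant``, ``Only identified by site``).  An LFQ value of 0
encodes "not measured" and is mapped to missing here, since a zero cannot
enter the downstream log2 transform.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GoccAnnotation, LogIntensityMatrix, StudyDesign, _norm_term

logger = logging.getLogger(__name__)

LFQ_PREFIX = "LFQ intensity "
FLAG_COLUMNS = {
    "flag_reverse": "Reverse",
    "flag_contaminant": "Potential contaminant",
    "flag_site_only": "Only identified by site",
}


@dataclass
class ProteinTable:
    """Parsed protein-group records: metadata + raw-scale intensities.

    ``meta`` has one row per protein group with columns ``protein_id``
    (representative accession = first in "Protein IDs"), ``protein_ids``,
    ``gene_names``, the three boolean QC flags, and ``gocc_terms``
    (frozenset, possibly empty).  ``intensities`` is a protein x sample
    DataFrame of raw LFQ values with NaN for unmeasured cells.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    extra: pd.DataFrame = None  # type: ignore[assignment]  # unparsed columns, kept opaque

    def __post_init__(self) -> None:
        if self.extra is None:
            self.extra = pd.DataFrame(index=self.meta.index)
        if (self.intensities.fillna(0).values < 0).any():
            raise ValueError("raw LFQ intensities must be non-negative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.meta["protein_id"])

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, row_mask) -> "ProteinTable":
        return ProteinTable(
            self.meta[row_mask].reset_index(drop=True),
            self.intensities[np.asarray(row_mask)],
            self.extra[row_mask].reset_index(drop=True),
        )

    def gocc_annotation(self) -> GoccAnnotation:
        return GoccAnnotation(
            {
                pid: frozenset(terms)
                for pid, terms in zip(self.meta["protein_id"], self.meta["gocc_terms"])
                if terms
            }
        )

    def log2_matrix(self, batch_of_sample: dict[str, str] | None = None) -> LogIntensityMatrix:
        """Log2-transform intensities; zeros/NaN become masked cells."""
        vals = self.intensities.copy()
        vals.index = pd.Index(self.protein_ids, name="protein_id")
        with np.errstate(divide="ignore"):
            logv = np.log2(vals.where(vals > 0))
        return LogIntensityMatrix(logv, stage="raw_log2", batch_of_sample=batch_of_sample or {})


def _parse_flag(col: pd.Series) -> pd.Series:
    # MaxQuant convention: the literal "+" is true, anything else false.
    return col.fillna("").astype(str).str.strip() == "+"


def read_protein_groups(path, design: StudyDesign | None = None) -> ProteinTable:
    """Parse a MaxQuant-dialect proteinGroups.txt table.

    Parameters
    ----------
    path:
        Tab-separated file with a header row; must contain "Protein IDs"
        and, if ``design`` is given, one "LFQ intensity <sample>" column
        per design sample.
    design:
        Optional design restricting (and validating) the sample columns.
        LFQ columns not in the design are ignored with a warning.

    Raises
    ------
    ValueError
        If "Protein IDs" is absent, or a design sample has no matching
        LFQ column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    if "Protein IDs" not in df.columns:
        raise ValueError(f"{path}: missing required column 'Protein IDs'")

    lfq_cols = {c[len(LFQ_PREFIX):]: c for c in df.columns if c.startswith(LFQ_PREFIX)}
    if design is not None:
        wanted = design.sample_ids
        absent = [s for s in wanted if s not in lfq_cols]
        if absent:
            raise ValueError(
                f"{path}: no 'LFQ intensity' column for design sample(s): {absent}"
            )
        ignored = sorted(set(lfq_cols) - set(wanted))
        if ignored:
            logger.warning("%s: ignoring %d LFQ column(s) not in design: %s",
                           path, len(ignored), ignored)
        lfq_cols = {s: lfq_cols[s] for s in wanted}
    if not lfq_cols:
        raise ValueError(f"{path}: no 'LFQ intensity <sample>' columns found")

    inten = pd.DataFrame(
        {s: pd.to_numeric(df[c], errors="coerce") for s, c in lfq_cols.items()}
    )
    inten = inten.where(inten > 0)  # 0 (and negatives, which error later) -> missing

    meta = pd.DataFrame(
        {
            "protein_ids": df["Protein IDs"].fillna(""),
            "protein_id": df["Protein IDs"].fillna("").str.split(";").str[0],
            "gene_names": df.get("Gene names", pd.Series("", index=df.index)).fillna(""),
        }
    )
    for attr, col in FLAG_COLUMNS.items():
        meta[attr] = _parse_flag(df[col]) if col in df.columns else False

    # GOCC terms may be embedded (semicolon-separated "GOCC names" style column).
    gocc_col = next((c for c in df.columns if _norm_term(c) in
                     ("gocc names", "gocc", "go cellular compartment")), None)
    if gocc_col is not None:
        meta["gocc_terms"] = [
            frozenset(_norm_term(t) for t in str(v).split(";") if t.strip())
            if pd.notna(v) else frozenset()
            for v in df[gocc_col]
        ]
    else:
        meta["gocc_terms"] = [frozenset()] * len(df)

    parsed = {"Protein IDs", "Gene names", *FLAG_COLUMNS.values(),
              *lfq_cols.values()} | ({gocc_col} if gocc_col else set())
    extra = df[[c for c in df.columns if c not in parsed]]
    return ProteinTable(meta, inten, extra)


def read_design(path, exclusions=(), untreated_label: str = "UT") -> StudyDesign:
    """Read a sample-design TSV (sample_id, batch, condition, donor, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return StudyDesign(df, exclusions=tuple(exclusions), untreated_label=untreated_label)


def write_design(design: StudyDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gocc(path) -> GoccAnnotation:
    """Read a long-format protein -> GOCC term TSV (columns protein_id, term)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "term"):
        if col not in df.columns:
            raise ValueError(f"{path}: GOCC table lacks column '{col}'")
    return GoccAnnotation.from_pairs(df[["protein_id", "term"]].itertuples(index=False))


def write_gocc(annot: GoccAnnotation, path) -> None:
    rows = [(pid, t) for pid, terms in sorted(annot.terms.items()) for t in sorted(terms)]
    pd.DataFrame(rows, columns=["protein_id", "term"]).to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write the per-(protein, batch, contrast) differential results TSV."""
    cols = ["protein_id", "gene", "batch", "contrast", "log2fc", "t_stat", "df",
            "p", "q", "hit"]
    out = results.copy()
    for c in cols:
        if c not in out.columns:
            out[c] = "" if c in ("gene",) else np.nan
    out[cols].to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["hit"] = df["hit"].astype(bool)
    return df


def write_matrix(m: LogIntensityMatrix, path) -> None:
    """Write a LogIntensityMatrix as TSV; masked cells serialise as 'NA'."""
    out = m.values.copy()
    out.index.name = f"protein_id#stage={m.stage}"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path, batch_of_sample: dict[str, str] | None = None) -> LogIntensityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    stage = "raw_log2"
    if df.index.name and "#stage=" in df.index.name:
        name, _, stage = df.index.name.partition("#stage=")
        df.index.name = name
    return LogIntensityMatrix(df, stage=stage, batch_of_sample=batch_of_sample or {})
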