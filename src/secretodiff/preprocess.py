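"""Filter cascade and normalization for LFQ secretome matrices.

The cascade mirrors a standard label-free secretomics workflow: QC-flag
removal (contaminants, decoys, site-only identifications), sample
exclusions, a replicate-presence filter per batch, log2 transform,
batch merge, restriction to secreted proteins by GOCC annotation, and
per-sample median centering.

Each step is available both as a scikit-learn style transformer (for
composition and get_params/set_params introspection) and as a plain
function wrapping it.
"""
from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    DEFAULT_SECRETED_TERMS,
    FilterReport,
    GoccAnnotation,
    LogIntensityMatrix,
    StudyDesign,
    _norm_term,
)
from .io import ProteinTable

logger = logging.getLogger(__name__)


class QCFilter(BaseEstimator, TransformerMixin):
    """Remove contaminant, decoy (reverse) and site-only protein rows.

    A row carrying several flags is counted once, with priority
    contaminant > reverse > site_only.  The removal counts are stored in
    ``report_`` after :meth:`transform`.
    """

    def fit(self, X: ProteinTable, y=None):
        return self

    def transform(self, X: ProteinTable) -> ProteinTable:
        m = X.meta
        contaminant = m["flag_contaminant"].to_numpy()
        reverse = m["flag_reverse"].to_numpy() & ~contaminant
        site_only = m["flag_site_only"].to_numpy() & ~contaminant & ~m["flag_reverse"].to_numpy()
        keep = ~(contaminant | reverse | site_only)
        self.report_ = {
            "contaminant": int(contaminant.sum()),
            "reverse": int(reverse.sum()),
            "site_only": int(site_only.sum()),
            "retained": int(keep.sum()),
        }
        return X.subset(keep)


def apply_qc_filters(table: ProteinTable) -> tuple[ProteinTable, dict[str, int]]:
    f = QCFilter()
    out = f.fit_transform(table)
    return out, f.report_


class PresenceFilter(BaseEstimator, TransformerMixin):
    """Keep proteins measured in >= ``tau`` of replicates of some condition.

    The fraction is compared exactly (2 of 4 passes tau = 0.5).  Groups
    are the (batch, condition) cells of the design, evaluated after
    exclusions so dropped samples never influence the fractions.
    """

    def __init__(self, design: StudyDesign, tau: float = 0.5):
        self.design = design
        self.tau = tau

    def fit(self, X: LogIntensityMatrix, y=None):
        if not (0 < self.tau <= 1):
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        return self

    def transform(self, X: LogIntensityMatrix) -> LogIntensityMatrix:
        self.fit(X)
        design = self.design.apply_exclusions()
        observed = ~X.mask
        tau = Fraction(self.tau).limit_denominator(10**6)
        keep = np.zeros(X.shape[0], dtype=bool)
        seen_any = False
        for batch in design.batches:
            for cond in design.conditions(batch):
                samples = [s for s in design.group_samples(batch, cond)
                           if s in observed.columns]
                if not samples:
                    continue
                seen_any = True
                n_measured = observed[samples].sum(axis=1).to_numpy()
                frac_ok = np.array(
                    [Fraction(int(k), len(samples)) >= tau for k in n_measured]
                )
                keep |= frac_ok
        if not seen_any:
            raise ValueError("no design condition group overlaps the matrix samples")
        self.n_removed_ = int((~keep).sum())
        return X.select_proteins(np.asarray(X.protein_ids)[keep])


def presence_filter(m: LogIntensityMatrix, design: StudyDesign,
                    tau: float = 0.5) -> LogIntensityMatrix:
    return PresenceFilter(design, tau).fit_transform(m)


class SecretedFilter(BaseEstimator, TransformerMixin):
    """Restrict proteins to those annotated with a secreted GOCC term.

    Terms are matched case-insensitively after whitespace normalization;
    unannotated proteins are removed (empty intersection).
    """

    def __init__(self, annotation: GoccAnnotation,
                 terms: tuple[str, ...] = DEFAULT_SECRETED_TERMS):
        self.annotation = annotation
        self.terms = terms

    def fit(self, X: LogIntensityMatrix, y=None):
        if not self.terms:
            raise ValueError("secreted term list must be non-empty")
        return self

    def transform(self, X: LogIntensityMatrix) -> LogIntensityMatrix:
        self.fit(X)
        wanted = {_norm_term(t) for t in self.terms}
        keep = [bool(self.annotation.terms_of(pid) & wanted) for pid in X.protein_ids]
        self.n_removed_ = int(len(keep) - sum(keep))
        return X.select_proteins(np.asarray(X.protein_ids)[np.asarray(keep)])


def restrict_secreted(m: LogIntensityMatrix, annot: GoccAnnotation,
                      terms=DEFAULT_SECRETED_TERMS) -> LogIntensityMatrix:
    return SecretedFilter(annot, tuple(terms)).fit_transform(m)


def merge_batches(first: LogIntensityMatrix, second: LogIntensityMatrix) -> LogIntensityMatrix:
    """Outer-join two batch matrices: union of proteins and samples.

    Cells for proteins absent from one batch are missing there.  Sample
    ids must be disjoint; per-sample batch labels are preserved.
    """
    overlap = set(first.sample_ids) & set(second.sample_ids)
    if overlap:
        raise ValueError(f"batches share sample ids: {sorted(overlap)}")
    values = first.values.join(second.values, how="outer")
    # preserve first-batch protein order, then new proteins in second-batch order
    order = list(first.values.index) + [p for p in second.values.index
                                        if p not in set(first.values.index)]
    values = values.loc[order]
    batch_of_sample = {**first.batch_of_sample, **second.batch_of_sample}
    return LogIntensityMatrix(values, stage="filtered", batch_of_sample=batch_of_sample)


class MedianCenterer(BaseEstimator, TransformerMixin):
    """Subtract each sample column's median over its observed values.

    Removes per-sample depth differences and discrete batch offsets.  A
    column with no observed values is an error (the matrix should have
    had degenerate samples excluded upstream).
    """

    def fit(self, X: LogIntensityMatrix, y=None):
        n_obs = (~X.mask).sum(axis=0)
        empty = [s for s, n in n_obs.items() if n == 0]
        if empty:
            raise ValueError(f"sample(s) with no observed values: {empty}")
        self.medians_ = X.values.median(axis=0, skipna=True)
        return self

    def transform(self, X: LogIntensityMatrix) -> LogIntensityMatrix:
        centered = X.values.sub(self.medians_, axis=1)
        return LogIntensityMatrix(centered, X.mask.copy(), "centered",
                                  dict(X.batch_of_sample))


def median_center(m: LogIntensityMatrix) -> LogIntensityMatrix:
    return MedianCenterer().fit(m).transform(m)


def preprocess_batch(
    table: ProteinTable,
    design: StudyDesign,
    batch: str,
    tau: float = 0.5,
    report: FilterReport | None = None,
) -> LogIntensityMatrix:
    """One batch's cascade: QC flags -> exclusions -> log2 -> presence filter."""
    report = report if report is not None else FilterReport()
    n_in = len(table)
    clean, qc_counts = apply_qc_filters(table)

    batch_design = StudyDesign(
        design.table[design.table["batch"] == batch],
        exclusions=design.exclusions,
        untreated_label=design.untreated_label,
    ).apply_exclusions()
    m = clean.log2_matrix({s: batch for s in batch_design.sample_ids})
    m = m.select_samples([s for s in batch_design.sample_ids if s in m.values.columns])

    pf = PresenceFilter(batch_design, tau)
    m = pf.fit_transform(m)
    report.record(batch, input_rows=n_in,
                  contaminant=qc_counts["contaminant"],
                  reverse=qc_counts["reverse"],
                  site_only=qc_counts["site_only"],
                  presence=pf.n_removed_,
                  retained=len(m.protein_ids))
    return m.with_stage("filtered")
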