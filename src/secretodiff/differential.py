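"""Per-protein differential secretion testing.

Each treatment is compared with the untreated group of the same batch
using Welch's unequal-variance t-test; p-values are Benjamini-Hochberg
adjusted within a configurable family (default: all proteins of one
(batch, treatment) contrast), and hits are proteins with q < 0.1 and
|log2 fold change| >= 1.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import LogIntensityMatrix, StudyDesign

logger = logging.getLogger(__name__)

#: variance floor used when both groups are constant but means differ
_VAR_FLOOR = np.finfo(float).eps


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sided t-test of ``x`` (treated) vs ``y`` (untreated).

    Returns ``(t, df, p)`` with ``t = (mean(x) - mean(y)) / sqrt(sx^2/nx +
    sy^2/ny)`` and Welch-Satterthwaite degrees of freedom.  Two groups
    with zero variance and identical means give ``(0, nx+ny-2, 1)`` by
    convention; zero variance with different means is computed with a
    machine-epsilon variance floor to preserve directionality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_test needs >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        vx = vy = _VAR_FLOOR
        se2x, se2y = vx / len(x), vy / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
        df = float(len(x) + len(y) - 2)
        return float(t), df, float(2 * stats.t.sf(abs(t), df))
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _welch_vectorized(xs: np.ndarray, ys: np.ndarray):
    """Row-wise Welch tests; falls back to :func:`welch_test` for
    zero-variance rows so the convention there applies."""
    res = stats.ttest_ind(xs, ys, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    df = np.asarray(res.df, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.nonzero(~np.isfinite(t) | ~np.isfinite(p))[0]
    for i in degenerate:
        t[i], df[i], p[i] = welch_test(xs[i], ys[i])
    return t, df, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_hits(results: pd.DataFrame, fdr_cut: float = 0.1,
              lfc_cut: float = 1.0) -> pd.DataFrame:
    """Flag hits: strict q < ``fdr_cut`` and inclusive |log2fc| >= ``lfc_cut``."""
    out = results.copy()
    out["hit"] = (out["q"] < fdr_cut) & (out["log2fc"].abs() >= lfc_cut)
    return out


class WelchDifferentialTester(BaseEstimator):
    """Fit Welch/BH differential tests on an imputed log2 matrix.

    Parameters
    ----------
    design:
        Study design; the untreated group of each batch is the reference.
    fdr_cut, lfc_cut:
        Hit thresholds (strict on q, inclusive on |log2fc|).
    family:
        BH family scope: ``"per_contrast"`` adjusts within each (batch,
        treatment) pair; ``"per_batch"`` pools all treatments of a batch.

    Attributes
    ----------
    results_:
        DataFrame with one row per (protein, batch, contrast):
        protein_id, batch, contrast, log2fc, t_stat, df, p, q, hit.
    """

    def __init__(self, design: StudyDesign, fdr_cut: float = 0.1,
                 lfc_cut: float = 1.0, family: str = "per_contrast"):
        self.design = design
        self.fdr_cut = fdr_cut
        self.lfc_cut = lfc_cut
        self.family = family

    def fit(self, X: LogIntensityMatrix, y=None):
        if self.family not in ("per_contrast", "per_batch"):
            raise ValueError("family must be 'per_contrast' or 'per_batch'")
        if X.mask.values.any():
            raise ValueError("differential testing expects a fully imputed matrix")
        design = self.design.apply_exclusions()
        rows = []
        for batch in design.batches:
            ut = [s for s in design.group_samples(batch, design.untreated_label)
                  if s in X.values.columns]
            if len(ut) < 2:
                logger.warning("batch %s: <2 untreated samples, skipped", batch)
                continue
            for treat in design.treatments(batch):
                tr = [s for s in design.group_samples(batch, treat)
                      if s in X.values.columns]
                if len(tr) < 2:
                    logger.warning("batch %s, %s: <2 treated samples, skipped",
                                   batch, treat)
                    continue
                xs = X.values[tr].to_numpy()
                ys = X.values[ut].to_numpy()
                t, df, p = _welch_vectorized(xs, ys)
                lfc = xs.mean(axis=1) - ys.mean(axis=1)
                contrast = f"{treat}_vs_{design.untreated_label}"
                rows.append(pd.DataFrame({
                    "protein_id": X.protein_ids, "batch": batch,
                    "contrast": contrast, "log2fc": lfc,
                    "t_stat": t, "df": df, "p": p,
                }))
        res = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        if res.empty:
            raise ValueError("no testable (batch, treatment) contrast found")
        keys = ["batch", "contrast"] if self.family == "per_contrast" else ["batch"]
        res["q"] = np.nan
        for _, idx in res.groupby(keys).groups.items():
            res.loc[idx, "q"] = bh_adjust(res.loc[idx, "p"].to_numpy())
        self.results_ = call_hits(res, self.fdr_cut, self.lfc_cut)
        return self

    def hit_table(self) -> pd.DataFrame:
        return self.results_[self.results_["hit"]].reset_index(drop=True)


def fit_contrasts(m: LogIntensityMatrix, design: StudyDesign,
                   fdr_cut: float = 0.1, lfc_cut: float = 1.0,
                   family: str = "per_contrast") -> pd.DataFrame:
    return WelchDifferentialTester(design, fdr_cut, lfc_cut, family).fit(m).results_


def overlap_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per treatment, the proteins hit in *both* batches and their count."""
    hits = results[results["hit"]]
    rows = []
    for contrast, grp in hits.groupby("contrast"):
        sets = {b: set(g["protein_id"]) for b, g in grp.groupby("batch")}
        batches = sorted(sets)
        shared = set.intersection(*sets.values()) if len(batches) >= 2 else set()
        rows.append({
            "contrast": contrast,
            "batches": ",".join(batches),
            "shared_proteins": ";".join(sorted(shared)),
            "n_shared": len(shared),
        })
    return pd.DataFrame(rows, columns=["contrast", "batches", "shared_proteins",
                                       "n_shared"])


def log2fc_heatmap_table(results: pd.DataFrame) -> pd.DataFrame:
    """Wide log2FC table of hit proteins x (batch, contrast) columns."""
    hit_proteins = results.loc[results["hit"], "protein_id"].unique()
    sub = results[results["protein_id"].isin(hit_proteins)]
    return sub.pivot_table(index="protein_id", columns=["batch", "contrast"],
                           values="log2fc")
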