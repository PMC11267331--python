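"""Targeted-assay arithmetic: multiplex/ELISA fold changes and qPCR 2^-dCt.

Multiplex fluorescence or ELISA OD readouts are normalized to whole
tissue protein content, expressed as fold change (FC) relative to the
untreated conditioned medium of the same batch, and screened with
two-sided unpaired Student's t-tests (significant p < 0.05, notable
p < 0.09).  CAM qPCR Ct values are converted to relative expression with
the 2^-dCt method against the mean of the PPIA and ACTB reference genes.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENES = ("PPIA", "ACTB")
SIGNIFICANT_P = 0.05
NOTABLE_P = 0.09


def _average_technical_duplicates(t: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in ("analyte", "donor", "condition", "batch") if c in t.columns]
    agg = {"raw_signal": "mean", "tissue_protein": "mean"}
    return t.groupby(keys, as_index=False, sort=False).agg(agg)


def normalize_fc(table: pd.DataFrame, untreated_label: str = "UT",
                 per_donor: bool = True) -> pd.DataFrame:
    """Tissue-protein-normalized fold changes vs untreated, per analyte/batch.

    Technical duplicates (same analyte/donor/condition/batch) are averaged
    first.  ``value = raw_signal / tissue_protein``; each donor's FC is
    its value over the batch's mean untreated value, and the condition FC
    is the mean over donors (``per_donor=False`` instead divides group
    means directly).

    Returns a long table with per-donor rows (columns ``fc``) plus the
    grouped summary accessible via :func:`fc_summary`.
    """
    required = {"analyte", "donor", "condition", "batch", "raw_signal", "tissue_protein"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"assay table lacks columns: {sorted(missing)}")
    if (table["tissue_protein"] <= 0).any():
        raise ValueError("tissue_protein must be > 0 for every row")
    t = _average_technical_duplicates(table)
    t["value"] = t["raw_signal"] / t["tissue_protein"]

    out = []
    for (analyte, batch), grp in t.groupby(["analyte", "batch"], sort=False):
        ut = grp.loc[grp["condition"] == untreated_label, "value"]
        if ut.empty:
            raise ValueError(
                f"no untreated ({untreated_label}) samples for analyte "
                f"{analyte!r} in batch {batch!r}"
            )
        ref = ut.mean()
        g = grp.copy()
        if per_donor:
            g["fc"] = g["value"] / ref
        else:
            group_means = g.groupby("condition")["value"].transform("mean")
            g["fc"] = group_means / ref
        out.append(g)
    return pd.concat(out, ignore_index=True)


def fc_summary(fc_table: pd.DataFrame) -> pd.DataFrame:
    """Mean FC per (analyte, batch, condition) — the heatmap table."""
    return (fc_table.groupby(["analyte", "batch", "condition"], as_index=False)
            ["fc"].mean())


def flag_changes(fc_table: pd.DataFrame, untreated_label: str = "UT",
                 equal_var: bool = True) -> pd.DataFrame:
    """Student's t-test of each treated group vs untreated, per analyte/batch.

    Flags: ``significant`` if p < 0.05, ``notable`` if 0.05 <= p < 0.09,
    empty otherwise.  Groups with fewer than 2 replicates are skipped
    with a logged reason.
    """
    rows = []
    for (analyte, batch), grp in fc_table.groupby(["analyte", "batch"], sort=False):
        ut = grp.loc[grp["condition"] == untreated_label, "value"].to_numpy()
        for cond, g in grp[grp["condition"] != untreated_label].groupby("condition"):
            vals = g["value"].to_numpy()
            if len(vals) < 2 or len(ut) < 2:
                logger.warning("%s/%s/%s: <2 replicates, skipped", analyte, batch, cond)
                continue
            if np.array_equal(np.sort(vals), np.sort(ut)):
                p = 1.0
            else:
                p = float(stats.ttest_ind(vals, ut, equal_var=equal_var).pvalue)
                if not np.isfinite(p):
                    p = 1.0
            flag = ("significant" if p < SIGNIFICANT_P
                    else "notable" if p < NOTABLE_P else "")
            rows.append({"analyte": analyte, "batch": batch, "condition": cond,
                         "mean_fc": float(g["fc"].mean()), "p": p, "flag": flag})
    return pd.DataFrame(rows, columns=["analyte", "batch", "condition",
                                       "mean_fc", "p", "flag"])


def ddct(ct_table: pd.DataFrame,
         reference_genes=DEFAULT_REFERENCE_GENES,
         untreated_label: str = "UT") -> pd.DataFrame:
    """Relative expression by the 2^-dCt method.

    ``dCt = Ct_gene - mean(Ct of reference genes in the same sample)``;
    ``rel = 2^-dCt``.  If the table carries a ``condition`` column, each
    gene's rel values are additionally normalized to the mean rel of the
    untreated group and reported as ``norm`` and ``log2fc``.

    Raises if any sample lacks a reference gene measurement.
    """
    required = {"gene", "sample", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    refs = ct_table[ct_table["gene"].isin(reference_genes)]
    ref_ct = refs.groupby("sample")["ct"].agg(["mean", "count"])
    bad = [s for s in ct_table["sample"].unique()
           if s not in ref_ct.index or ref_ct.loc[s, "count"] < len(reference_genes)]
    if bad:
        raise ValueError(f"sample(s) missing reference gene Ct: {sorted(map(str, bad))}")

    out = ct_table[~ct_table["gene"].isin(reference_genes)].copy()
    out["dct"] = out["ct"] - out["sample"].map(ref_ct["mean"])
    out["rel"] = 2.0 ** (-out["dct"])

    if "condition" in out.columns:
        parts = []
        for gene, grp in out.groupby("gene", sort=False):
            ut_rel = grp.loc[grp["condition"] == untreated_label, "rel"]
            g = grp.copy()
            if ut_rel.empty:
                logger.warning("gene %s: no untreated samples; FC not computed", gene)
                g["norm"] = np.nan
            else:
                g["norm"] = g["rel"] / ut_rel.mean()
            g["log2fc"] = np.log2(g["norm"])
            parts.append(g)
        out = pd.concat(parts, ignore_index=True)
    return out
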