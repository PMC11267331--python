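"""Core in-memory containers for the secretomics pipeline.

The central object is :class:`LogIntensityMatrix`, a proteins x samples
matrix of log2 LFQ intensities with an explicit missingness mask, tagged
with the processing stage it has reached.  Sample metadata lives in
:class:`StudyDesign`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Processing stages a LogIntensityMatrix may carry, in pipeline order.
STAGES = ("raw_log2", "filtered", "centered", "imputed")

#: GOCC terms defining the secreted-protein universe.
DEFAULT_SECRETED_TERMS = (
    "secretory granule",
    "secretory granule lumen",
    "secretory granule membrane",
    "extracellular vesicle",
    "extracellular space",
    "extracellular exosome",
)


def _norm_term(t: str) -> str:
    return " ".join(str(t).split()).lower()


@dataclass(frozen=True)
class StudyDesign:
    """Sample -> (batch, condition, donor, replicate) mapping with exclusions.

    Parameters
    ----------
    table:
        DataFrame with columns ``sample_id``, ``batch``, ``condition``,
        ``donor``, ``replicate``.  Sample ids must be unique.
    exclusions:
        ``(donor, condition)`` pairs whose samples are dropped before any
        analysis (e.g. untreated term samples of donors with >95% of
        entries unmeasured).
    untreated_label:
        Condition label of the untreated reference group.
    """

    table: pd.DataFrame
    exclusions: tuple[tuple[str, str], ...] = ()
    untreated_label: str = "UT"

    REQUIRED = ("sample_id", "batch", "condition", "donor", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table lacks columns: {missing}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample_id(s) in design: {dupes}")
        tbl = self.table.copy()
        for c in ("sample_id", "batch", "condition", "donor"):
            tbl[c] = tbl[c].astype(str)
        object.__setattr__(self, "table", tbl.reset_index(drop=True))
        object.__setattr__(
            self,
            "exclusions",
            tuple((str(d), str(c)) for d, c in self.exclusions),
        )

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def batches(self) -> list[str]:
        return list(pd.unique(self.table["batch"]))

    def conditions(self, batch: str | None = None) -> list[str]:
        t = self.table if batch is None else self.table[self.table["batch"] == batch]
        return list(pd.unique(t["condition"]))

    def treatments(self, batch: str | None = None) -> list[str]:
        return [c for c in self.conditions(batch) if c != self.untreated_label]

    def apply_exclusions(self) -> "StudyDesign":
        """Drop excluded (donor, condition) samples; returns a new design."""
        if not self.exclusions:
            return self
        tbl = self.table
        drop = pd.Series(False, index=tbl.index)
        for donor, cond in self.exclusions:
            drop |= (tbl["donor"] == donor) & (tbl["condition"] == cond)
        return replace(self, table=tbl[~drop].reset_index(drop=True), exclusions=())

    def group_samples(self, batch: str, condition: str) -> list[str]:
        t = self.table
        sel = (t["batch"] == batch) & (t["condition"] == condition)
        return list(t.loc[sel, "sample_id"])

    def subset(self, sample_ids) -> "StudyDesign":
        keep = self.table["sample_id"].isin(list(sample_ids))
        return replace(self, table=self.table[keep].reset_index(drop=True))

    def validate_contrasts(self) -> None:
        """Every (batch, condition) group needs >=2 samples for a Welch test."""
        d = self.apply_exclusions()
        for b in d.batches:
            for c in d.conditions(b):
                n = len(d.group_samples(b, c))
                if n < 2:
                    raise ValueError(
                        f"group (batch={b}, condition={c}) has {n} sample(s); "
                        "contrasts involving it are undefined"
                    )


@dataclass
class LogIntensityMatrix:
    """Proteins x samples log2 intensities with an explicit missingness mask.

    ``values`` holds NaN wherever ``mask`` is True; the two are kept
    consistent at construction.  ``stage`` records how far through the
    pipeline the matrix has travelled; only the imputation stage may fill
    masked cells.
    """

    values: pd.DataFrame
    mask: pd.DataFrame = None  # type: ignore[assignment]
    stage: str = "raw_log2"
    batch_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.mask is None:
            self.mask = self.values.isna()
        self.mask = self.mask.astype(bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values shapes differ")
        # enforce mask <=> NaN
        v = self.values.copy()
        v[self.mask.values] = np.nan
        self.values = v
        if not self.values.index.is_unique:
            raise ValueError("duplicate protein ids in matrix index")
        self.values.index.name = "protein_id"
        self.mask.index.name = "protein_id"

    # -- convenience -------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_observed(self) -> int:
        return int((~self.mask.values).sum())

    def with_stage(self, stage: str) -> "LogIntensityMatrix":
        return LogIntensityMatrix(self.values, self.mask, stage, dict(self.batch_of_sample))

    def select_proteins(self, ids) -> "LogIntensityMatrix":
        ids = list(ids)
        return LogIntensityMatrix(
            self.values.loc[ids], self.mask.loc[ids], self.stage, dict(self.batch_of_sample)
        )

    def select_samples(self, ids) -> "LogIntensityMatrix":
        ids = list(ids)
        return LogIntensityMatrix(
            self.values[ids], self.mask[ids], self.stage, dict(self.batch_of_sample)
        )

    def copy(self) -> "LogIntensityMatrix":
        return LogIntensityMatrix(
            self.values.copy(), self.mask.copy(), self.stage, dict(self.batch_of_sample)
        )


@dataclass
class FilterReport:
    """Row-count accounting for the filter cascade, per batch.

    Invariant: ``input_rows == retained + sum(removed.values())`` for each
    batch (checked by :meth:`assert_conserving`).
    """

    per_batch: dict[str, dict[str, int]] = field(default_factory=dict)

    STAGES = ("contaminant", "reverse", "site_only", "presence", "non_secreted")

    def record(self, batch: str, **counts: int) -> None:
        d = self.per_batch.setdefault(
            batch, {"input_rows": 0, "retained": 0, **{s: 0 for s in self.STAGES}}
        )
        for k, v in counts.items():
            d[k] = d.get(k, 0) + int(v)

    def assert_conserving(self) -> None:
        for batch, d in self.per_batch.items():
            removed = sum(d[s] for s in self.STAGES)
            if d["input_rows"] != d["retained"] + removed:
                raise AssertionError(
                    f"filter report not conserving for batch {batch}: "
                    f"{d['input_rows']} != {d['retained']} + {removed}"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for batch, d in self.per_batch.items():
            rows.append({"batch": batch, **d})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GoccAnnotation:
    """protein_id -> set of GOCC term strings (whitespace/case normalised)."""

    terms: dict[str, frozenset[str]]

    @staticmethod
    def from_pairs(pairs) -> "GoccAnnotation":
        d: dict[str, set[str]] = {}
        for pid, term in pairs:
            d.setdefault(str(pid), set()).add(_norm_term(term))
        return GoccAnnotation({k: frozenset(v) for k, v in d.items()})

    def terms_of(self, protein_id: str) -> frozenset[str]:
        return self.terms.get(protein_id, frozenset())

    def is_annotated(self, protein_id: str, term_list) -> bool:
        wanted = {_norm_term(t) for t in term_list}
        return bool(self.terms_of(protein_id) & wanted)

    def merged_with(self, other: "GoccAnnotation") -> "GoccAnnotation":
        """Union of annotations; ``other`` wins on conflicting protein ids."""
        d = dict(self.terms)
        d.update(other.terms)
        return GoccAnnotation(d)
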