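"""Condition-aware imputation of left-censored missing values.

Label-free proteomics intensities are missing not at random: low-abundance
proteins drop below the detection limit, so missing values are best
replaced by draws from a narrow normal distribution shifted *below* the
observed intensities.  Two branches are distinguished per (protein,
condition) group:

* **major** — at least ``presence_cut`` of the group's replicates were
  measured, so the value was probably near the detection limit: draw from
  ``Normal(mu - 0.5*sd, (0.3*sd)^2)``.
* **minor** — the protein was consistently absent in the condition: draw
  from the stronger down-shift ``Normal(mu - 1.8*sd, (0.3*sd)^2)``.

The reference mean ``mu`` and standard deviation ``sd`` are taken from
the observed values of a configurable scope (default: the missing cell's
sample column).  Draws are reproducible: each cell's stream is seeded
from (seed, protein id, sample id), so results do not depend on row or
column order.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import LogIntensityMatrix, StudyDesign

SCOPES = ("per_sample", "per_condition", "global")


@dataclass(frozen=True)
class ImputationParams:
    """Down-shift parameters, all in units of the reference SD."""

    shift_major: float = 0.5
    shift_minor: float = 1.8
    width: float = 0.3
    presence_cut: float = 0.5
    scope: str = "per_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shift_major, self.shift_minor, self.width) <= 0:
            raise ValueError("shifts and width must be > 0")
        if not (0 < self.presence_cut <= 1):
            raise ValueError("presence_cut must be in (0, 1]")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")


@dataclass
class ImputationAudit:
    """Per (protein, condition): branch taken and number of cells imputed."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["protein_id", "batch", "condition", "branch", "n_imputed",
                     "n_measured", "n_replicates"],
        )


def _cell_rng(seed: int, protein_id: str, sample_id: str) -> np.random.Generator:
    # crc32 keys keep streams stable under row/column reordering
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(seed), zlib.crc32(protein_id.encode()), zlib.crc32(sample_id.encode())]
        )
    )


def sample_downshifted(mu: float, sd: float, shift: float, width: float,
                       rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw from the down-shifted normal ``N(mu - shift*sd, (width*sd)^2)``."""
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"reference SD must be positive and finite, got {sd}")
    return rng.normal(mu - shift * sd, width * sd, size=size)


class DownShiftImputer(BaseEstimator, TransformerMixin):
    """Impute masked cells from condition-aware down-shifted normals.

    Parameters mirror :class:`ImputationParams`; the study design supplies
    the (batch, condition) grouping used for the branch decision.  After
    :meth:`transform`, ``audit_`` holds an :class:`ImputationAudit`.
    """

    def __init__(self, design: StudyDesign, shift_major: float = 0.5,
                 shift_minor: float = 1.8, width: float = 0.3,
                 presence_cut: float = 0.5, scope: str = "per_sample",
                 seed: int = 0):
        self.design = design
        self.shift_major = shift_major
        self.shift_minor = shift_minor
        self.width = width
        self.presence_cut = presence_cut
        self.scope = scope
        self.seed = seed

    @property
    def params(self) -> ImputationParams:
        return ImputationParams(self.shift_major, self.shift_minor, self.width,
                                self.presence_cut, self.scope, self.seed)

    def fit(self, X: LogIntensityMatrix, y=None):
        self.params  # validates
        if X.stage != "centered":
            raise ValueError(f"imputation expects a 'centered' matrix, got {X.stage!r}")
        return self

    # -- reference statistics ---------------------------------------------
    def _reference_stats(self, X: LogIntensityMatrix, design: StudyDesign):
        """(mu, sd) per sample column, per the configured scope."""
        obs = X.values
        if self.scope == "per_sample":
            mu = obs.mean(axis=0, skipna=True)
            sd = obs.std(axis=0, ddof=1, skipna=True)
        elif self.scope == "global":
            flat = obs.values[~X.mask.values]
            mu = pd.Series(float(np.mean(flat)), index=obs.columns)
            sd = pd.Series(float(np.std(flat, ddof=1)), index=obs.columns)
        else:  # per_condition
            mu = pd.Series(index=obs.columns, dtype=float)
            sd = pd.Series(index=obs.columns, dtype=float)
            for batch in design.batches:
                for cond in design.conditions(batch):
                    samples = [s for s in design.group_samples(batch, cond)
                               if s in obs.columns]
                    if not samples:
                        continue
                    flat = obs[samples].values[~X.mask[samples].values]
                    mu[samples] = float(np.mean(flat)) if flat.size else np.nan
                    sd[samples] = float(np.std(flat, ddof=1)) if flat.size > 1 else np.nan
        # only columns that actually receive draws need a valid reference SD
        needs = X.mask.any(axis=0)
        bad = [s for s in obs.columns
               if needs[s] and (not np.isfinite(sd[s]) or sd[s] <= 0)]
        if bad:
            raise ValueError(f"reference SD undefined or zero for sample(s): {bad}")
        return mu, sd

    def transform(self, X: LogIntensityMatrix) -> LogIntensityMatrix:
        self.fit(X)
        design = self.design.apply_exclusions()
        mu, sd = self._reference_stats(X, design)

        values = X.values.copy()
        mask = X.mask
        audit = ImputationAudit()
        col_ix = {s: i for i, s in enumerate(values.columns)}
        vals = values.to_numpy()
        msk = mask.to_numpy()

        for batch in design.batches:
            for cond in design.conditions(batch):
                samples = [s for s in design.group_samples(batch, cond)
                           if s in col_ix]
                if not samples:
                    continue
                cols = np.array([col_ix[s] for s in samples])
                sub_missing = msk[:, cols]
                n_missing_row = sub_missing.sum(axis=1)
                n_rep = len(samples)
                for ri in np.nonzero(n_missing_row)[0]:
                    n_meas = n_rep - int(n_missing_row[ri])
                    major = (n_meas / n_rep) >= self.presence_cut
                    shift = self.shift_major if major else self.shift_minor
                    pid = values.index[ri]
                    for s, ci in zip(samples, cols):
                        if not msk[ri, ci]:
                            continue
                        rng = _cell_rng(self.seed, str(pid), str(s))
                        vals[ri, ci] = sample_downshifted(
                            float(mu[s]), float(sd[s]), shift, self.width, rng, 1
                        )[0]
                    audit.records.append({
                        "protein_id": pid, "batch": batch, "condition": cond,
                        "branch": "major" if major else "minor",
                        "n_imputed": int(n_missing_row[ri]),
                        "n_measured": n_meas, "n_replicates": n_rep,
                    })

        out = pd.DataFrame(vals, index=values.index, columns=values.columns)
        remaining = out.isna()
        if remaining.values.any():
            # cells in samples outside every design group stay missing — not allowed
            raise ValueError(
                "cells outside any design (batch, condition) group remain missing"
            )
        self.audit_ = audit
        return LogIntensityMatrix(out, remaining, "imputed", dict(X.batch_of_sample))


def impute(m: LogIntensityMatrix, design: StudyDesign,
           params: ImputationParams | None = None
           ) -> tuple[LogIntensityMatrix, ImputationAudit]:
    params = params or ImputationParams()
    imp = DownShiftImputer(design, params.shift_major, params.shift_minor,
                           params.width, params.presence_cut, params.scope,
                           params.seed)
    out = imp.fit_transform(m)
    return out, imp.audit_
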