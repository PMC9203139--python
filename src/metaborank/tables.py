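"""Core data containers for the metabolite-prioritization pipeline.

The central payload is :class:`MetaboliteTable`, a samples x metabolites
abundance matrix carrying per-metabolite annotations (super-pathway,
sub-pathway, drug-metabolite flag) and a per-cell below-limit-of-detection
mask. Values live either on the raw ion-count scale or on the log10 scale;
a scale tag guards against double transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOG10 = "log10"

ANNOTATION_COLUMNS = ("name", "super_pathway", "sub_pathway", "is_drug_metabolite")


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundance matrix with annotations and LOD mask.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns metabolite ids. On the raw
        scale every observed (non-masked) cell must be strictly positive.
    below_lod
        Boolean DataFrame of the same shape; True marks a cell recorded
        below the metabolite's lower limit of detection (treated as
        missing until imputation).
    annotations
        DataFrame indexed by metabolite id with columns ``name``,
        ``super_pathway``, ``sub_pathway`` and ``is_drug_metabolite``.
    scale
        Either ``"raw"`` or ``"log10"``.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    annotations: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in (RAW, LOG10):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.values.shape != self.below_lod.shape:
            raise ValueError(
                f"values {self.values.shape} and below_lod {self.below_lod.shape} "
                "shapes disagree"
            )
        if not self.values.index.equals(self.below_lod.index) or not self.values.columns.equals(
            self.below_lod.columns
        ):
            raise ValueError("values and below_lod must share index and columns")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate metabolite ids")
        missing_ann = set(self.values.columns) - set(self.annotations.index)
        if missing_ann:
            raise ValueError(f"metabolites without annotations: {sorted(missing_ann)[:5]}")
        for col in ANNOTATION_COLUMNS:
            if col not in self.annotations.columns:
                raise ValueError(f"annotation column {col!r} missing")
        if self.scale == RAW and self.values.size:
            observed = self.values.to_numpy()[~self.below_lod.to_numpy(dtype=bool)]
            if observed.size and not (observed > 0).all():
                raise ValueError("raw-scale observed values must be strictly positive")

    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(
            values=self.values.copy(),
            below_lod=self.below_lod.copy(),
            annotations=self.annotations.copy(),
            scale=self.scale,
        )

    def subset_metabolites(self, keep: Sequence) -> "MetaboliteTable":
        """Return a table restricted to ``keep`` (order preserved as given)."""
        keep = list(keep)
        return MetaboliteTable(
            values=self.values.loc[:, keep],
            below_lod=self.below_lod.loc[:, keep],
            annotations=self.annotations.loc[keep],
            scale=self.scale,
        )

    def with_scale(self, values: pd.DataFrame, scale: str) -> "MetaboliteTable":
        return MetaboliteTable(
            values=values,
            below_lod=self.below_lod.copy(),
            annotations=self.annotations.copy(),
            scale=scale,
        )


@dataclass
class SampleMetadata:
    """Per-sample metadata with a mandatory binary 28-day mortality outcome.

    ``frame`` is indexed by sample id; the outcome column holds 1 for
    patients who died within 28 days of ICU admission and 0 otherwise.
    Additional clinical covariates (age, sex, severity scores, ...) may be
    present as extra columns.
    """

    frame: pd.DataFrame
    outcome_column: str = "died"

    def __post_init__(self) -> None:
        if self.outcome_column not in self.frame.columns:
            raise ValueError(f"outcome column {self.outcome_column!r} missing")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        outcome = self.frame[self.outcome_column]
        if outcome.isna().any():
            raise ValueError("outcome must be non-missing for every sample")
        vals = set(pd.unique(outcome))
        if not vals <= {0, 1}:
            raise ValueError(f"outcome must be binary 0/1, got values {sorted(vals)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def outcome(self) -> pd.Series:
        return self.frame[self.outcome_column].astype(int)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())


def check_aligned(table: MetaboliteTable, metadata: SampleMetadata) -> None:
    """Raise if the table and metadata do not share identical sample order."""
    if not table.sample_ids.equals(metadata.sample_ids):
        raise ValueError("table and metadata sample ids differ or are ordered differently")
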