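"""Metabolite-table preprocessing: drug exclusion, LOD filtering, log10,
imputation, and fold-safe standardization.

The fixed stage order is: drug-metabolite exclusion -> below-LOD filter
(strict >10% rule by default) -> log10 transform -> imputation of the
remaining below-LOD cells. Imputation fill values are computed per
metabolite from observed cells only, on the current (analysis) scale;
within cross-validation the same operations are re-fit on training folds
only (see :func:`standardize_fold` and the cv engine).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import LOG10, RAW, MetaboliteTable

logger = logging.getLogger(__name__)

IMPUTATION_STRATEGIES = ("half_min_per_metabolite", "min_per_metabolite", "lod_over_sqrt2")


@dataclass
class PreprocessConfig:
    lod_exclusion_fraction: float = 0.10
    imputation_strategy: str = "half_min_per_metabolite"
    scaling: str = "standardize"  # or "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lod_exclusion_fraction <= 1.0:
            raise ValueError("lod_exclusion_fraction must be in [0, 1]")
        if self.imputation_strategy not in IMPUTATION_STRATEGIES:
            raise ValueError(f"unknown imputation strategy {self.imputation_strategy!r}")
        if self.scaling not in ("standardize", "none"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass
class PreprocessReport:
    """Audit trail of the filtering cascade."""

    n_input_metabolites: int
    n_after_drug_exclusion: int
    n_after_lod_filter: int
    removed_drug_metabolites: list
    removed_lod_metabolites: list
    imputed_cell_count: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "drug_exclusion", "lod_filter", "imputation"],
                "n_metabolites": [
                    self.n_input_metabolites,
                    self.n_after_drug_exclusion,
                    self.n_after_lod_filter,
                    self.n_after_lod_filter,
                ],
                "n_removed": [
                    0,
                    len(self.removed_drug_metabolites),
                    len(self.removed_lod_metabolites),
                    0,
                ],
                "n_cells_imputed": [0, 0, 0, self.imputed_cell_count],
            }
        )


def exclude_drug_metabolites(table: MetaboliteTable) -> tuple[MetaboliteTable, list]:
    """Drop metabolites flagged as drug metabolites; order of the rest preserved."""
    flags = table.annotations.loc[table.metabolite_ids, "is_drug_metabolite"].astype(bool)
    removed = list(table.metabolite_ids[flags.to_numpy()])
    keep = list(table.metabolite_ids[~flags.to_numpy()])
    if not keep:
        warnings.warn("all metabolites are drug metabolites; resulting table is empty")
    return table.subset_metabolites(keep), removed


def filter_below_lod(
    table: MetaboliteTable, config: PreprocessConfig
) -> tuple[MetaboliteTable, list]:
    """Remove metabolites whose below-LOD fraction strictly exceeds the threshold.

    The decision uses the mask only, never the numeric values; surviving
    metabolites keep their flagged cells (imputed later).
    """
    frac = table.below_lod.mean(axis=0)
    removed_mask = frac > config.lod_exclusion_fraction
    removed = list(table.metabolite_ids[removed_mask.to_numpy()])
    keep = list(table.metabolite_ids[~removed_mask.to_numpy()])
    return table.subset_metabolites(keep), removed


def log10_transform(table: MetaboliteTable) -> MetaboliteTable:
    """Base-10 logarithm of observed cells; sets the scale tag to log10."""
    if table.scale != RAW:
        raise ValueError(f"log10_transform requires a raw-scale table, got {table.scale!r}")
    vals = table.values.to_numpy(dtype=float, copy=True)
    observed = ~table.below_lod.to_numpy()
    bad = observed & ~(vals > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "nonpositive observed value at sample "
            f"{table.sample_ids[i]!r}, metabolite {table.metabolite_ids[j]!r}"
        )
    vals[observed] = np.log10(vals[observed])
    out = pd.DataFrame(vals, index=table.sample_ids, columns=table.metabolite_ids)
    return table.with_scale(out, LOG10)


def compute_fill_values(
    values: pd.DataFrame, mask: pd.DataFrame, strategy: str
) -> pd.Series:
    """Per-metabolite imputation fill value from observed cells only."""
    vals = values.to_numpy(dtype=float)
    observed = ~mask.to_numpy()
    if not observed.any(axis=0).all():
        missing = values.columns[~observed.any(axis=0)]
        raise ValueError(f"metabolite(s) with zero observed values: {list(missing)[:5]}")
    masked = np.where(observed, vals, np.inf)
    col_min = masked.min(axis=0)
    if strategy == "half_min_per_metabolite":
        fill = col_min / 2.0
    elif strategy == "min_per_metabolite":
        fill = col_min
    elif strategy == "lod_over_sqrt2":
        fill = col_min / np.sqrt(2.0)
    else:  # pragma: no cover - guarded by PreprocessConfig
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    return pd.Series(fill, index=values.columns)


def impute_missing(table: MetaboliteTable, config: PreprocessConfig) -> MetaboliteTable:
    """Fill below-LOD cells per metabolite; observed cells are untouched."""
    fill = compute_fill_values(table.values, table.below_lod, config.imputation_strategy)
    vals = table.values.to_numpy(dtype=float, copy=True)
    mask = table.below_lod.to_numpy()
    vals = np.where(mask, np.broadcast_to(fill.to_numpy(), vals.shape), vals)
    out = table.copy()
    out.values.iloc[:, :] = vals
    return out


def run_preprocessing(
    table: MetaboliteTable, config: PreprocessConfig | None = None
) -> tuple[MetaboliteTable, PreprocessReport]:
    """Full-data preprocessing cascade with an audit report.

    Returns a log10-scale, fully imputed table. For cross-validation the
    imputation/scaling parameters must instead be re-fit per training fold
    (cv engine responsibility); the drug/LOD filters are mask-based sample-
    independent decisions and are applied once here.
    """
    config = config or PreprocessConfig()
    n_input = table.n_metabolites
    table, removed_drug = exclude_drug_metabolites(table)
    n_drug = table.n_metabolites
    table, removed_lod = filter_below_lod(table, config)
    n_lod = table.n_metabolites
    table = log10_transform(table)
    n_imputed = int(table.below_lod.to_numpy().sum())
    table = impute_missing(table, config)
    report = PreprocessReport(
        n_input_metabolites=n_input,
        n_after_drug_exclusion=n_drug,
        n_after_lod_filter=n_lod,
        removed_drug_metabolites=removed_drug,
        removed_lod_metabolites=removed_lod,
        imputed_cell_count=n_imputed,
    )
    logger.info(
        "preprocessing: %d -> %d (drug) -> %d (LOD), %d cells imputed",
        n_input, n_drug, n_lod, n_imputed,
    )
    return table, report


@dataclass
class ScalingParams:
    mean: pd.Series
    sd: pd.Series  # sample SD (ddof=1); zero-variance columns recorded as 0


def standardize_fold(
    train_values: pd.DataFrame, apply_values: list[pd.DataFrame] | None = None
) -> tuple[pd.DataFrame, list[pd.DataFrame], ScalingParams]:
    """Standardize columns using training-fold statistics only.

    Mean/SD (sample SD, ddof=1) are computed on ``train_values``; the same
    parameters are applied to each frame in ``apply_values`` so no test-fold
    information leaks into scaling. Columns constant in the training fold
    are mapped to all-zeros (a warning is emitted) rather than dropped, so
    metabolite indexing stays stable across folds.
    """
    if train_values.shape[0] < 2:
        raise ValueError("standardize_fold needs at least 2 training samples")
    mean = train_values.mean(axis=0)
    sd = train_values.std(axis=0, ddof=1)
    zero_var = sd <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance training column(s) scaled to all-zeros"
        )
    safe_sd = sd.where(~zero_var, 1.0)

    def _apply(frame: pd.DataFrame) -> pd.DataFrame:
        scaled = (frame - mean) / safe_sd
        if zero_var.any():
            scaled.loc[:, zero_var[zero_var].index] = 0.0
        return scaled

    scaled_train = _apply(train_values)
    scaled_apply = [_apply(f) for f in (apply_values or [])]
    params = ScalingParams(mean=mean, sd=sd.where(~zero_var, 0.0))
    return scaled_train, scaled_apply, params
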