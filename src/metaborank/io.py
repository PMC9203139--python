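"""Delimited-text I/O for metabolite tables, metadata and ground truth.

The on-disk layout is three sidecar files sharing ids:

* matrix: samples x metabolites, first column ``sample_id``; below-LOD /
  missing cells hold a sentinel (default ``<LOD``) or are empty;
* annotations: keyed by ``metabolite_id`` with ``name``, ``super_pathway``,
  ``sub_pathway``, ``is_drug_metabolite`` columns;
* metadata: keyed by ``sample_id`` with an outcome column (values {0, 1} or
  {survived, died}) plus optional covariates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SyntheticCohort, SyntheticTruth
from .tables import MetaboliteTable, SampleMetadata, RAW

DEFAULT_SENTINEL = "<LOD"

_OUTCOME_ALIASES = {"0": 0, "1": 1, "survived": 0, "died": 1}


def _read_delimited(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        return pd.read_csv(path, sep=None, engine="python", index_col=0)
    return pd.read_csv(path, sep=sep, index_col=0)


def read_metabolite_table(
    matrix_path,
    annotation_path,
    metadata_path,
    sentinel: str = DEFAULT_SENTINEL,
    sep: str | None = None,
    outcome_column: str = "died",
    scale: str = RAW,
) -> tuple[MetaboliteTable, SampleMetadata]:
    """Read and align the three sidecar files.

    The delimiter is auto-detected unless ``sep`` is forced. Sentinel or
    empty cells populate the below-LOD mask and are never parsed as numbers.
    """
    raw = pd.read_csv(matrix_path, sep=sep, index_col=0, dtype=str, engine="python" if sep is None else "c")
    if raw.index.has_duplicates:
        raise ValueError("duplicate sample ids in matrix")
    if raw.columns.has_duplicates:
        raise ValueError("duplicate metabolite ids in matrix")
    mask = raw.isna() | raw.apply(lambda c: c.str.strip() == sentinel)
    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        observed = ~mask[col]
        try:
            values.loc[observed, col] = raw.loc[observed, col].astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric abundance cell in metabolite {col!r}: {exc}") from exc

    annotations = _read_delimited(annotation_path, sep)
    missing_cols = {"super_pathway", "is_drug_metabolite"} - set(annotations.columns)
    if missing_cols:
        raise ValueError(f"annotation file missing columns: {sorted(missing_cols)}")
    if "name" not in annotations.columns:
        annotations["name"] = annotations.index
    if "sub_pathway" not in annotations.columns:
        annotations["sub_pathway"] = ""
    annotations["is_drug_metabolite"] = annotations["is_drug_metabolite"].astype(bool)
    unmatched = set(values.columns) - set(annotations.index)
    if unmatched:
        raise ValueError(f"metabolites without annotations: {sorted(unmatched)[:5]}")
    annotations = annotations.loc[values.columns]

    meta = _read_delimited(metadata_path, sep)
    if outcome_column not in meta.columns:
        raise ValueError(f"metadata missing outcome column {outcome_column!r}")
    missing_samples = set(values.index) - set(meta.index)
    if missing_samples:
        raise ValueError(f"metadata missing sample(s): {sorted(missing_samples)}")
    meta = meta.loc[values.index]
    outcome = meta[outcome_column].astype(str).str.strip().str.lower().map(_OUTCOME_ALIASES)
    if outcome.isna().any():
        bad = meta.index[outcome.isna()][0]
        raise ValueError(f"unrecognized outcome value for sample {bad!r}")
    meta = meta.copy()
    meta[outcome_column] = outcome.astype(int)

    for frame in (values, mask):
        frame.index.name = "sample_id"
        frame.columns.name = "metabolite_id"
    annotations.index.name = "metabolite_id"
    meta.index.name = "sample_id"

    table = MetaboliteTable(
        values=values.astype(float),
        below_lod=mask.astype(bool),
        annotations=annotations,
        scale=scale,
    )
    metadata = SampleMetadata(frame=meta, outcome_column=outcome_column)
    return table, metadata


def write_metabolite_table(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    outdir,
    sentinel: str = DEFAULT_SENTINEL,
    sep: str = ",",
) -> dict[str, Path]:
    """Write matrix/annotations/metadata in the dialect ``read_metabolite_table`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    disp = table.values.astype(object)
    disp = disp.where(~table.below_lod, sentinel)
    paths = {
        "matrix": outdir / "metabolite_matrix.csv",
        "annotations": outdir / "metabolite_annotations.csv",
        "metadata": outdir / "sample_metadata.csv",
    }
    disp.to_csv(paths["matrix"], sep=sep, index_label="sample_id")
    table.annotations.to_csv(paths["annotations"], sep=sep, index_label="metabolite_id")
    metadata.frame.to_csv(paths["metadata"], sep=sep, index_label="sample_id")
    return paths


def write_truth(truth: SyntheticTruth, outdir, sep: str = ",") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "ground_truth.csv"
    truth.to_frame().to_csv(path, sep=sep, index=False)
    return path


def write_cohort(cohort: SyntheticCohort, outdir, sentinel: str = DEFAULT_SENTINEL) -> dict[str, Path]:
    paths = write_metabolite_table(cohort.table, cohort.metadata, outdir, sentinel=sentinel)
    paths["truth"] = write_truth(cohort.truth, outdir)
    return paths
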