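"""End-to-end orchestration: cohort -> preprocessing -> tuned models ->
consensus ranking -> report bundle.

The bundle mirrors the study's table/figure data: a preprocessing audit, a
per-family performance table, the consensus (ensemble-score) table with
per-group medians and univariate p-values, a cross-method agreement table,
the PCA variance profile and hierarchical-clustering orders for the heatmap,
plus a run manifest sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .consensus import (
    ConsensusConfig,
    EnsembleRanking,
    SelectionMatrix,
    build_selection_matrix,
    ensemble_importance,
    pairwise_agreement,
)
from .cv import CVConfig, FittedModelResult, make_fold_plan, prepare_fold_data, tune_model
from .io import read_metabolite_table, write_cohort
from .models import default_registry
from .preprocess import (
    PreprocessConfig,
    PreprocessReport,
    exclude_drug_metabolites,
    filter_below_lod,
    impute_missing,
    log10_transform,
    standardize_fold,
)
from .stats import (
    baseline_comparison_table,
    hierarchical_cluster_order,
    pca_variance_profile,
    univariate_metabolite_table,
)
from .synthetic import SyntheticConfig, SyntheticCohort, generate_cohort
from .tables import MetaboliteTable, SampleMetadata, check_aligned

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Exactly one input mode: ``synthetic`` (a :class:`SyntheticConfig`) or
    the three input paths. ``seed`` drives fold randomization and every
    stochastic model fit.
    """

    synthetic: SyntheticConfig | None = None
    matrix_path: str | None = None
    annotation_path: str | None = None
    metadata_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    families: list[str] | None = None
    top_n: int = 20
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        paths = [self.matrix_path, self.annotation_path, self.metadata_path]
        has_paths = all(p is not None for p in paths)
        if (self.synthetic is None) == (not has_paths):
            raise ValueError("set exactly one of: synthetic config, or all three input paths")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All pipeline outputs: delimited-ready frames plus live objects."""

    preprocess_report: PreprocessReport
    performance: pd.DataFrame  # one row per family: PR/ROC AUC, sensitivity, specificity
    fold_metrics: pd.DataFrame  # long format: family, repeat, fold, metrics
    consensus_table: pd.DataFrame  # ensemble score + medians + univariate p
    agreement_intersection: pd.DataFrame | None
    agreement_jaccard: pd.DataFrame | None
    univariate_table: pd.DataFrame
    baseline_table: pd.DataFrame
    variance_profile: pd.DataFrame
    heatmap_matrix: pd.DataFrame
    heatmap_sample_order: list
    heatmap_metabolite_order: list
    manifest: dict
    ranking: EnsembleRanking
    selection_matrix: SelectionMatrix
    model_results: dict[str, FittedModelResult]
    table: MetaboliteTable  # preprocessed (log10, imputed)
    metadata: SampleMetadata
    cohort: SyntheticCohort | None


def _load_inputs(config: PipelineConfig) -> tuple[MetaboliteTable, SampleMetadata, SyntheticCohort | None]:
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        return cohort.table, cohort.metadata, cohort
    table, metadata = read_metabolite_table(
        config.matrix_path, config.annotation_path, config.metadata_path
    )
    return table, metadata, None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis; deterministic given the config (incl. seed)."""
    t0 = time.time()
    table, metadata, cohort = _load_inputs(config)
    check_aligned(table, metadata)
    outcomes = metadata.outcome
    logger.info("cohort: %d samples (%d events), %d metabolites",
                table.n_samples, int(outcomes.sum()), table.n_metabolites)

    # preprocessing cascade; imputation is deferred to the fold level for CV
    n_input = table.n_metabolites
    table_nd, removed_drug = exclude_drug_metabolites(table)
    table_f, removed_lod = filter_below_lod(table_nd, config.preprocess)
    table_log = log10_transform(table_f)
    n_masked = int(table_log.below_lod.to_numpy().sum())
    table_imputed = impute_missing(table_log, config.preprocess)
    report = PreprocessReport(
        n_input_metabolites=n_input,
        n_after_drug_exclusion=table_nd.n_metabolites,
        n_after_lod_filter=table_f.n_metabolites,
        removed_drug_metabolites=removed_drug,
        removed_lod_metabolites=removed_lod,
        imputed_cell_count=n_masked,
    )
    logger.info("preprocessing: %d -> %d -> %d metabolites, %d cells imputed",
                n_input, table_nd.n_metabolites, table_f.n_metabolites, n_masked)

    # cross-validation plan and fold-safe preprocessed data (shared by all families)
    cv_cfg = dataclasses.replace(config.cv, seed=config.seed)
    fold_plan = make_fold_plan(outcomes, cv_cfg)
    fold_data = prepare_fold_data(table_log, outcomes, fold_plan, config.preprocess)

    registry = default_registry(config.families, top_n=config.top_n)
    results: dict[str, FittedModelResult] = {}
    for spec in registry:
        t_fam = time.time()
        results[spec.family_id] = tune_model(
            spec, table_log, outcomes, fold_plan, cv_cfg,
            preprocess_config=config.preprocess, fold_data=fold_data, seed=config.seed,
        )
        logger.info("tuned %s in %.1fs (best %s, mean PR-AUC %.3f)",
                    spec.family_id, time.time() - t_fam,
                    results[spec.family_id].best_hyperparams,
                    results[spec.family_id].fold_metrics["pr_auc"].mean())

    performance = pd.DataFrame([r.summary for r in results.values()])
    performance.insert(0, "best_hyperparams", [repr(r.best_hyperparams) for r in results.values()])
    fold_metrics = pd.concat(
        [r.fold_metrics.assign(family=fid) for fid, r in results.items()], ignore_index=True
    )

    # consensus ranking over the post-filter universe
    selections = {fid: set(r.selected_ids) for fid, r in results.items()}
    sel_matrix = build_selection_matrix(selections, table_log.metabolite_ids)
    names = table_log.annotations["name"].to_dict()
    ranking = ensemble_importance(sel_matrix, config.consensus, names=names)

    univariate = univariate_metabolite_table(table_imputed, outcomes)
    consensus_table = ranking.frame.join(
        table_log.annotations[["name", "super_pathway"]]
    ).join(univariate[["median_survived", "q1_survived", "q3_survived",
                       "median_died", "q1_died", "q3_died", "p_value"]])
    consensus_table = consensus_table[
        ["name", "super_pathway", "score", "n_models_selecting", "rank", "prioritized",
         "median_survived", "q1_survived", "q3_survived",
         "median_died", "q1_died", "q3_died", "p_value"]
    ]

    if sel_matrix.n_models >= 2:
        inter, jac = pairwise_agreement(sel_matrix)
    else:
        inter = jac = None

    # figure-data analogs
    profile = pca_variance_profile(table_imputed.values.to_numpy(), standardize=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z_scaled, _, _ = standardize_fold(table_imputed.values, [])
    sample_order = hierarchical_cluster_order(z_scaled.to_numpy())
    metab_order = hierarchical_cluster_order(z_scaled.to_numpy().T)
    heatmap_sample_order = [table_imputed.sample_ids[i] for i in sample_order]
    heatmap_metab_order = [table_imputed.metabolite_ids[j] for j in metab_order]

    baseline = baseline_comparison_table(metadata.frame, metadata.outcome_column)

    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_samples": int(table.n_samples),
        "n_events": int(outcomes.sum()),
        "n_metabolites_input": n_input,
        "n_metabolites_analyzed": int(table_log.n_metabolites),
        "runtime_seconds": round(time.time() - t0, 2),
    }

    return ReportBundle(
        preprocess_report=report,
        performance=performance,
        fold_metrics=fold_metrics,
        consensus_table=consensus_table,
        agreement_intersection=inter,
        agreement_jaccard=jac,
        univariate_table=univariate,
        baseline_table=baseline,
        variance_profile=profile.to_frame(),
        heatmap_matrix=z_scaled,
        heatmap_sample_order=heatmap_sample_order,
        heatmap_metabolite_order=heatmap_metab_order,
        manifest=manifest,
        ranking=ranking,
        selection_matrix=sel_matrix,
        model_results=results,
        table=table_imputed,
        metadata=metadata,
        cohort=cohort,
    )


def write_report_bundle(bundle: ReportBundle, outdir, overwrite: bool = False) -> dict[str, Path]:
    """Write one delimited file per table plus a structured manifest.

    Floating-point cells are printed at 6 significant digits for diffability.
    Refuses to overwrite an existing bundle unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.yaml"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    outdir.mkdir(parents=True, exist_ok=True)

    fmt = "%.6g"
    paths: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame, index: bool = True, label: str | None = None) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, float_format=fmt, index=index, index_label=label)
        paths[name] = path

    _write("preprocess_report", bundle.preprocess_report.to_frame(), index=False)
    _write("model_performance", bundle.performance, label="family")
    _write("fold_metrics", bundle.fold_metrics, index=False)
    _write("consensus_table", bundle.consensus_table, label="metabolite_id")
    _write("univariate_table", bundle.univariate_table, label="metabolite_id")
    _write("baseline_table", bundle.baseline_table, index=False)
    _write("variance_profile", bundle.variance_profile, index=False)
    _write("heatmap_matrix", bundle.heatmap_matrix, label="sample_id")
    if bundle.agreement_jaccard is not None:
        _write("agreement_jaccard", bundle.agreement_jaccard, label="model")
        _write("agreement_intersection", bundle.agreement_intersection, label="model")
    orders = pd.DataFrame(
        {
            "axis": ["sample"] * len(bundle.heatmap_sample_order)
            + ["metabolite"] * len(bundle.heatmap_metabolite_order),
            "position": list(range(len(bundle.heatmap_sample_order)))
            + list(range(len(bundle.heatmap_metabolite_order))),
            "id": list(bundle.heatmap_sample_order) + list(bundle.heatmap_metabolite_order),
        }
    )
    _write("heatmap_orders", orders, index=False)

    with open(manifest_path, "w") as fh:
        yaml.safe_dump(bundle.manifest, fh, sort_keys=True, default_flow_style=False)
    paths["manifest"] = manifest_path
    return paths
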