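"""Run the full consensus pipeline and rank metabolites by ensemble score.

Uses a reduced configuration (4 of the 8 families, 3 CV repeats) so the
script finishes in well under a minute; the defaults (8 families, 50
repeats) follow the same path. The ensemble importance score of a
metabolite is the fraction of model families whose innate feature selection
ranked it highly; metabolites scoring >= 0.5 are the prioritized set.
"""

from metaborank import CVConfig, PipelineConfig, SyntheticConfig, run_pipeline

config = PipelineConfig(
    synthetic=SyntheticConfig(seed=1),
    cv=CVConfig(n_folds=5, n_repeats=3, seed=1),
    families=["lasso_logistic", "nearest_shrunken_centroids", "pls_da", "random_forest"],
    seed=1,
)
bundle = run_pipeline(config)

print("per-family cross-validated performance (mean over 15 test folds):")
cols = ["pr_auc_mean", "roc_auc_mean", "sensitivity_mean", "specificity_mean"]
print(bundle.performance[cols].round(3).to_string())

print("\ntop of the consensus table (score = fraction of 4 families selecting):")
top = bundle.consensus_table.head(10)
planted = set(bundle.cohort.truth.effect_metabolite_ids)
for mid, row in top.iterrows():
    mark = "*" if mid in planted else " "
    print(f"  {mark} {mid}  score {row.score:.2f}  univariate p {row.p_value:.2g}")
print("    (* = planted ground-truth effect metabolite)")

prioritized = bundle.ranking.prioritized_ids
hits = len(set(prioritized) & planted)
print(f"\nprioritized (score >= 0.5): {len(prioritized)} metabolites, "
      f"{hits} of {len(planted)} planted effects among them")
# A no-skill classifier would reach PR-AUC = 0.42 (the event rate); families
# scoring well above that are finding the planted signal, and the consensus
# score concentrates on the ground-truth metabolites.
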