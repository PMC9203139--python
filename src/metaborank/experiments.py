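"""Planted-signal recovery experiment on synthetic cohorts.

Generates cohorts with known effect metabolites, runs the full consensus
pipeline, and measures whether the ensemble importance score separates the
planted metabolites from the nulls. This is the package's end-to-end
validation instrument: the unavailable study data cannot anchor the real
rankings, but a generator with ground truth can show that the machinery
recovers signal under the study's dimensions (60 samples, 411 metabolites,
42% event rate, 13 planted effects).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusConfig
from .cv import CVConfig
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import SyntheticConfig

logger = logging.getLogger(__name__)


@dataclass
class RecoveryResult:
    per_seed: pd.DataFrame
    """One row per seed: mean planted/null score, top-k overlap, counts."""

    @property
    def n_seeds_planted_above_null(self) -> int:
        return int((self.per_seed["mean_planted_score"] > self.per_seed["mean_null_score"]).sum())

    @property
    def median_top_k_overlap(self) -> float:
        return float(self.per_seed["top_k_overlap"].median())


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(int(master_seed) % (2**31))
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def run_recovery_experiment(
    seeds: list[int],
    synthetic_config: SyntheticConfig | None = None,
    n_repeats: int = 5,
    n_folds: int = 5,
    families: list[str] | None = None,
    top_n: int = 20,
) -> RecoveryResult:
    """Run the pipeline once per seed and score ground-truth recovery.

    ``top_k_overlap`` counts planted metabolites among the top k ensemble
    ranks, where k = number of planted metabolites (ties resolved by the
    ranking's own deterministic order).
    """
    rows = []
    for seed in seeds:
        base = synthetic_config or SyntheticConfig()
        synth = dataclasses.replace(base, seed=int(seed))
        config = PipelineConfig(
            synthetic=synth,
            cv=CVConfig(n_folds=n_folds, n_repeats=n_repeats, seed=int(seed)),
            families=families,
            top_n=top_n,
            consensus=ConsensusConfig(),
            seed=int(seed),
        )
        bundle = run_pipeline(config)
        truth = bundle.cohort.truth
        planted = [m for m in truth.effect_metabolite_ids if m in bundle.ranking.frame.index]
        scores = bundle.ranking.scores
        null_ids = scores.index.difference(planted)
        k = len(truth.effect_metabolite_ids)
        top_k = list(bundle.ranking.frame.sort_values("rank").index[:k])
        overlap = len(set(top_k) & set(truth.effect_metabolite_ids))
        rows.append(
            {
                "seed": int(seed),
                "n_planted": k,
                "n_planted_in_universe": len(planted),
                "mean_planted_score": float(scores.loc[planted].mean()) if planted else 0.0,
                "mean_null_score": float(scores.loc[null_ids].mean()),
                "top_k_overlap": overlap,
                "n_metabolites_analyzed": int(len(scores)),
            }
        )
        logger.info("seed %d: planted %.3f vs null %.3f, top-%d overlap %d",
                    seed, rows[-1]["mean_planted_score"], rows[-1]["mean_null_score"], k, overlap)
    return RecoveryResult(per_seed=pd.DataFrame(rows))
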