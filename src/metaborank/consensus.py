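"""Ensemble importance score: the fraction of model families selecting a
metabolite.

Each of M fitted model families contributes a set of metabolites it
"selected or ranked highly" via its innate feature-selection mechanism. A
metabolite's ensemble importance score is the fraction of families that
selected it — a value on the lattice {0, 1/M, ..., 1}. Metabolites with a
score at or above the threshold (default 0.5, inclusive) are the
prioritized set; ranking is by descending score with alphabetical
tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class SelectionMatrix:
    """Models x metabolites boolean indicator of selection."""

    indicator: pd.DataFrame  # index model_ids, columns metabolite_ids, dtype bool

    def __post_init__(self) -> None:
        if self.indicator.index.has_duplicates:
            raise ValueError("duplicate model ids")
        if self.indicator.columns.has_duplicates:
            raise ValueError("duplicate metabolite ids")
        if self.indicator.shape[1] == 0:
            raise ValueError("metabolite universe is empty")

    @property
    def model_ids(self) -> pd.Index:
        return self.indicator.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.indicator.columns

    @property
    def n_models(self) -> int:
        return self.indicator.shape[0]


@dataclass
class ConsensusConfig:
    score_threshold: float = 0.5
    tie_break: str = "alphabetical"
    include_models: list | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")
        if self.tie_break != "alphabetical":
            raise ValueError("only alphabetical tie-breaking is supported")


@dataclass
class EnsembleRanking:
    """Per-metabolite ensemble score, rank and prioritization flag.

    ``frame`` columns: score (exact multiple of 1/M), n_models_selecting,
    rank (contiguous from 1), prioritized (score >= threshold).
    """

    frame: pd.DataFrame
    n_models: int
    threshold: float

    @property
    def scores(self) -> pd.Series:
        return self.frame["score"]

    @property
    def prioritized_ids(self) -> list:
        ordered = self.frame.sort_values("rank")
        return list(ordered.index[ordered["prioritized"]])


def build_selection_matrix(
    selections: Mapping[str, Iterable], metabolite_universe: Sequence
) -> SelectionMatrix:
    """Indicator matrix from per-model selection sets.

    Duplicate ids within one model's set are counted once; a model with an
    empty selection contributes an all-false row (it still counts in the
    ensemble denominator).
    """
    universe = pd.Index(metabolite_universe)
    if len(universe) == 0:
        raise ValueError("metabolite universe is empty")
    if universe.has_duplicates:
        raise ValueError("duplicate ids in metabolite universe")
    rows = {}
    for model_id, sel in selections.items():
        sel_set = set(sel)
        outside = sel_set - set(universe)
        if outside:
            raise ValueError(
                f"model {model_id!r} selected ids outside the universe: {sorted(outside)[:5]}"
            )
        rows[model_id] = universe.isin(sel_set)
    indicator = pd.DataFrame.from_dict(rows, orient="index", dtype=bool)
    indicator.columns = universe
    return SelectionMatrix(indicator=indicator)


def ensemble_importance(
    matrix: SelectionMatrix,
    config: ConsensusConfig | None = None,
    names: Mapping | None = None,
) -> EnsembleRanking:
    """Score each metabolite by the fraction of models selecting it.

    Invariant to model-row order; monotone (an extra selecting model never
    lowers a score). ``names`` optionally maps metabolite ids to display
    names used for alphabetical tie-breaking.
    """
    config = config or ConsensusConfig()
    ind = matrix.indicator
    if config.include_models is not None:
        ind = ind.loc[list(config.include_models)]
    m = ind.shape[0]
    if m < 1:
        raise ValueError("at least one model is required")
    n_sel = ind.sum(axis=0).astype(int)
    score = n_sel / m
    frame = pd.DataFrame(
        {"score": score, "n_models_selecting": n_sel}, index=matrix.metabolite_ids
    )
    frame["prioritized"] = frame["score"] >= config.score_threshold
    display = (
        frame.index.to_series().map(lambda i: str(names.get(i, i)))
        if names
        else frame.index.to_series().astype(str)
    )
    order = sorted(frame.index, key=lambda i: (-frame.at[i, "score"], display[i].lower()))
    frame = frame.loc[order]
    frame["rank"] = np.arange(1, len(frame) + 1)
    return EnsembleRanking(frame=frame, n_models=m, threshold=config.score_threshold)


def apply_threshold(ranking: EnsembleRanking, config: ConsensusConfig | None = None) -> list:
    """Prioritized metabolites: score >= threshold (inclusive), in rank order."""
    tau = (config or ConsensusConfig()).score_threshold
    ordered = ranking.frame.sort_values("rank")
    return list(ordered.index[ordered["score"] >= tau])


def rank_metabolites(
    ranking: EnsembleRanking, config: ConsensusConfig | None = None
) -> pd.DataFrame:
    """Ranked table: descending score, alphabetical within ties; deterministic."""
    return ranking.frame.sort_values("rank").copy()


def pairwise_agreement(matrix: SelectionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-method agreement: intersection sizes and Jaccard indices.

    Jaccard of two empty selections is defined as 1 (perfect agreement on
    selecting nothing). Both outputs are symmetric with unit diagonal
    Jaccard.
    """
    if matrix.n_models < 2:
        raise ValueError("pairwise agreement needs >= 2 models")
    ind = matrix.indicator.to_numpy(dtype=bool)
    m = ind.shape[0]
    inter = ind.astype(int) @ ind.astype(int).T
    sizes = ind.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    ids = matrix.model_ids
    return (
        pd.DataFrame(inter, index=ids, columns=ids),
        pd.DataFrame(jac, index=ids, columns=ids),
    )
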