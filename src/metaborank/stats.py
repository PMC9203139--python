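"""Descriptive and univariate cohort statistics.

Covers the baseline-table style comparisons (Wilcoxon rank-sum for
continuous variables, likelihood-ratio chi-squared for categoricals),
per-metabolite group medians/IQRs, PCA variance profiling of the
metabolome, and hierarchical-clustering leaf orders for heatmap layout.
Univariate p-values are descriptive companions to the ensemble score — the
prioritization instrument — so no multiplicity adjustment is applied to
them; a Benjamini-Hochberg column is emitted alongside for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .tables import MetaboliteTable


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks for ties.

    Exact enumeration when the combined sample is small (n <= 12, no ties);
    otherwise the normal approximation with tie correction and continuity
    correction. Returns (U statistic for group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def likelihood_ratio_chi2(table_2x2) -> tuple[float, float]:
    """Likelihood-ratio (G) test on a 2x2 table, 1 degree of freedom.

    G = 2 * sum O * ln(O/E); empty cells contribute 0. Raises on a zero
    margin (expected counts undefined).
    """
    obs = np.asarray(table_2x2, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("all margins must be positive")
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    p = float(sps.chi2.sf(g, df=1))
    return float(g), p


def group_median_iqr(values, outcome) -> pd.DataFrame:
    """Per-group median and quartiles (linear-interpolation convention).

    Returns a frame indexed by group (0/1) with columns median, q1, q3.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=int)
    rows = {}
    for g in (0, 1):
        gv = v[y == g]
        if gv.size == 0:
            raise ValueError(f"group {g} is empty")
        q1, med, q3 = np.percentile(gv, [25, 50, 75], method="linear")
        rows[g] = {"median": med, "q1": q1, "q3": q3}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class VarianceProfile:
    """Per-component PCA variance fractions and cumulative profile."""

    fractions: np.ndarray
    cumulative: np.ndarray

    def n_components_for(self, target_fraction: float) -> int:
        """Smallest k whose cumulative explained variance reaches the target."""
        if not 0.0 < target_fraction <= 1.0:
            raise ValueError("target fraction must be in (0, 1]")
        idx = np.searchsorted(self.cumulative, target_fraction - 1e-12)
        return int(min(idx, len(self.cumulative) - 1)) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.fractions) + 1),
                "variance_fraction": self.fractions,
                "cumulative_fraction": self.cumulative,
            }
        )


def pca_variance_profile(matrix, standardize: bool = True) -> VarianceProfile:
    """Explained-variance fractions from the singular values of the centered
    (optionally per-column standardized) matrix."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    if not np.any(X != 0):
        raise ValueError("constant matrix has no principal components")
    s = np.linalg.svd(X, compute_uv=False)
    var = s**2
    fractions = var / var.sum()
    return VarianceProfile(fractions=fractions, cumulative=np.cumsum(fractions))


def hierarchical_cluster_order(
    matrix, metric: str = "euclidean", linkage: str = "complete"
) -> np.ndarray:
    """Dendrogram leaf order for the rows of ``matrix``.

    Agglomerative clustering with the given distance and linkage (defaults:
    Euclidean, complete). scipy's linkage is deterministic for a fixed input
    order, which provides the tie-breaking convention.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    return hierarchy.leaves_list(Z)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (step-up), reported for reference only."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = n - rank_from_end
        running = min(running, p[idx] * n / k)
        adj[idx] = running
    return np.clip(adj, 0.0, 1.0)


def univariate_metabolite_table(
    table: MetaboliteTable, outcome: pd.Series, back_transform: bool = True
) -> pd.DataFrame:
    """Per-metabolite group medians (IQR) and Wilcoxon rank-sum p-values.

    ``table`` is the preprocessed (log10, imputed) table; with
    ``back_transform`` the medians/IQRs are reported on the raw ion-count
    scale (10**value) to match how normalized levels are printed.
    """
    y = outcome.loc[table.sample_ids].astype(int).to_numpy()
    vals = table.values
    rows = []
    for mid in table.metabolite_ids:
        col = vals[mid].to_numpy(dtype=float)
        disp = np.power(10.0, col) if (back_transform and table.scale == "log10") else col
        gm = group_median_iqr(disp, y)
        _, p = wilcoxon_rank_sum(col[y == 0], col[y == 1])
        rows.append(
            {
                "metabolite_id": mid,
                "median_survived": gm.loc[0, "median"],
                "q1_survived": gm.loc[0, "q1"],
                "q3_survived": gm.loc[0, "q3"],
                "median_died": gm.loc[1, "median"],
                "q1_died": gm.loc[1, "q1"],
                "q3_died": gm.loc[1, "q3"],
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("metabolite_id")
    out["p_adjusted_bh"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def baseline_comparison_table(metadata_frame: pd.DataFrame, outcome_column: str = "died") -> pd.DataFrame:
    """Baseline-characteristics comparison between survivors and non-survivors.

    Numeric covariates: median (IQR) per group, Wilcoxon rank-sum p.
    Binary/categorical covariates: counts per group, likelihood-ratio
    chi-squared p (binary 2x2 only; multi-level variables are dichotomized
    level-by-level is NOT done — they are skipped with a note).
    """
    y = metadata_frame[outcome_column].astype(int)
    rows = []
    for col in metadata_frame.columns:
        if col == outcome_column:
            continue
        series = metadata_frame[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            a, b = series[y == 0].dropna(), series[y == 1].dropna()
            _, p = wilcoxon_rank_sum(a, b)
            gm = group_median_iqr(series.dropna(), y.loc[series.dropna().index])
            rows.append(
                {
                    "variable": col,
                    "type": "continuous",
                    "survived": f"{gm.loc[0,'median']:.6g} ({gm.loc[0,'q1']:.6g}, {gm.loc[0,'q3']:.6g})",
                    "died": f"{gm.loc[1,'median']:.6g} ({gm.loc[1,'q1']:.6g}, {gm.loc[1,'q3']:.6g})",
                    "p_value": p,
                }
            )
        else:
            levels = series.dropna().unique()
            if len(levels) != 2:
                rows.append(
                    {"variable": col, "type": "skipped (not binary)", "survived": "", "died": "", "p_value": np.nan}
                )
                continue
            pos = levels.max()
            tab = [
                [int(((series == pos) & (y == 0)).sum()), int(((series != pos) & (y == 0)).sum())],
                [int(((series == pos) & (y == 1)).sum()), int(((series != pos) & (y == 1)).sum())],
            ]
            try:
                _, p = likelihood_ratio_chi2(tab)
            except ValueError:
                p = np.nan
            rows.append(
                {
                    "variable": col,
                    "type": "categorical",
                    "survived": f"{tab[0][0]}/{tab[0][0] + tab[0][1]}",
                    "died": f"{tab[1][0]}/{tab[1][0] + tab[1][1]}",
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
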