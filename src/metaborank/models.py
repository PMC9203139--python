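"""Classifier families with a uniform fit / risk-score / innate-importance
contract.

Eight families form the default registry: PLS discriminant analysis,
nearest shrunken centroids, random forests, support vector machines, random
feature-subspace k-nearest neighbours, adaptive boosting, Lasso logistic
regression and (ridge-leaning elastic-net) penalized logistic regression.
Each family exposes

* ``score(X)`` — a per-sample value in [0, 1], monotone in the predicted
  probability of death (larger = higher risk), and
* an innate importance vector (nonnegative, one entry per metabolite)
  together with a "selected" mask: the model's intrinsic sparse support for
  sparse families, or the top-N importances otherwise.

Standard estimators come from scikit-learn; nearest shrunken centroids and
random-subspace kNN are implemented here because no installed estimator
exposes the required posterior scores and innate importances.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

DEFAULT_FAMILY_ORDER = (
    "pls_da",
    "nearest_shrunken_centroids",
    "random_forest",
    "svm",
    "random_knn",
    "ada_boost_bag",
    "lasso_logistic",
    "penalized_logistic",
)

# families with an intrinsic sparse solution (eligible for native selection)
NATIVE_SPARSE_FAMILIES = frozenset({"lasso_logistic", "nearest_shrunken_centroids"})


@dataclass
class ModelSpec:
    """One classifier family: id, hyperparameter grid and selection rule.

    ``grid`` is an ordered list of hyperparameter dicts, simplest (most
    regularized / fewest components) first; grid-search ties are broken in
    favour of earlier entries.
    """

    family_id: str
    grid: list[dict]
    selection_mode: str = "top_n"  # "native" | "top_n"
    top_n: int = 20

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError(f"{self.family_id}: hyperparameter grid must be non-empty")
        if self.selection_mode not in ("native", "top_n"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.selection_mode == "native" and self.family_id not in NATIVE_SPARSE_FAMILIES:
            raise ValueError(
                f"{self.family_id} has no intrinsic sparse solution; use top_n selection"
            )
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass
class ImportanceVector:
    """Nonnegative per-metabolite importances plus the selected mask."""

    importances: pd.Series
    selected: pd.Series
    family_id: str

    def __post_init__(self) -> None:
        if not self.importances.index.equals(self.selected.index):
            raise ValueError("importances and selected must share an index")
        vals = self.importances.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("importances must be finite and nonnegative")

    @property
    def selected_ids(self) -> list:
        return list(self.selected.index[self.selected.to_numpy(dtype=bool)])


def default_registry(
    families: Sequence[str] | None = None, top_n: int = 20
) -> list[ModelSpec]:
    """The eight-family default registry, in deterministic order.

    ``families`` restricts the registry (order preserved from the default).
    """
    penalty_path = [{"C": float(c)} for c in np.logspace(-2, 1, 10)]
    specs = {
        "pls_da": ModelSpec(
            "pls_da", [{"n_components": k} for k in range(1, 6)], "top_n", top_n
        ),
        "nearest_shrunken_centroids": ModelSpec(
            "nearest_shrunken_centroids",
            [{"shrink": d} for d in (3.0, 2.4, 1.9, 1.5, 1.2, 0.9, 0.6, 0.4, 0.2, 0.0)],
            "native",
            top_n,
        ),
        "random_forest": ModelSpec(
            "random_forest",
            [{"max_features": "sqrt"}, {"max_features": 0.25}],
            "top_n",
            top_n,
        ),
        "svm": ModelSpec("svm", [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}], "top_n", top_n),
        "random_knn": ModelSpec(
            "random_knn", [{"n_neighbors": 5}, {"n_neighbors": 3}], "top_n", top_n
        ),
        "ada_boost_bag": ModelSpec(
            "ada_boost_bag", [{"n_estimators": 50}, {"n_estimators": 100}], "top_n", top_n
        ),
        "lasso_logistic": ModelSpec("lasso_logistic", list(penalty_path), "native", top_n),
        "penalized_logistic": ModelSpec(
            "penalized_logistic", list(penalty_path), "top_n", top_n
        ),
    }
    chosen = list(DEFAULT_FAMILY_ORDER) if families is None else list(families)
    unknown = [f for f in chosen if f not in specs]
    if unknown:
        raise ValueError(f"unknown model families: {unknown}")
    return [specs[f] for f in chosen]


# ----------------------------------------------------------------------
# fitted-model wrapper


@dataclass
class FittedModel:
    family_id: str
    hyperparams: dict
    feature_names: pd.Index
    _score_fn: Callable[[np.ndarray], np.ndarray]
    _importance_fn: Callable[[], np.ndarray]
    spec: ModelSpec

    def score(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Per-sample risk score in [0, 1]; larger = higher predicted death risk."""
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if arr.shape[1] != len(self.feature_names):
            raise ValueError("feature dimension mismatch")
        s = np.asarray(self._score_fn(arr), dtype=float)
        return np.clip(s, 0.0, 1.0)

    def raw_importances(self) -> np.ndarray:
        imp = np.asarray(self._importance_fn(), dtype=float)
        return np.maximum(imp, 0.0)


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    if isinstance(X, pd.DataFrame):
        names = X.columns
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = pd.Index([f"f{j}" for j in range(arr.shape[1])])
    yv = np.asarray(y, dtype=int)
    if np.isnan(arr).any():
        raise ValueError("X must be complete (imputed) before fitting")
    if len(np.unique(yv)) < 2:
        raise ValueError("y must contain both classes")
    return arr, yv, names


def _seed_int(seed: int, family_id: str) -> int:
    # crc32 (not hash()) so the derived seed is stable across processes
    ss = np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(family_id.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_model(spec: ModelSpec, X, y, hyperparams: dict | None = None, seed: int = 0) -> FittedModel:
    """Fit one family at the given hyperparameters (default: first grid point).

    X must be complete (post-imputation) and, for distance/penalty-based
    families, standardized. Deterministic given ``seed``.
    """
    hp = dict(spec.grid[0]) if hyperparams is None else dict(hyperparams)
    arr, yv, names = _as_xy(X, y)
    builder = _FAMILY_BUILDERS.get(spec.family_id)
    if builder is None:
        raise ValueError(f"no builder for family {spec.family_id!r}")
    score_fn, importance_fn = builder(arr, yv, hp, _seed_int(seed, spec.family_id))
    return FittedModel(
        family_id=spec.family_id,
        hyperparams=hp,
        feature_names=names,
        _score_fn=score_fn,
        _importance_fn=importance_fn,
        spec=spec,
    )


# ----------------------------------------------------------------------
# family builders: (X, y, hyperparams, seed) -> (score_fn, importance_fn)


def _build_pls_da(X, y, hp, seed):
    n_components = int(hp.get("n_components", 2))
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, y.astype(float))

    def score_fn(Xnew):
        # predicted 0/1 response squashed by a strictly monotone sigmoid:
        # preserves ranking (clipping would tie extreme predictions) and
        # keeps the 0.5 decision point at a predicted response of 0.5
        return expit(4.0 * (model.predict(Xnew).ravel() - 0.5))

    def importance_fn():
        return _vip_scores(model, X.shape[1])

    return score_fn, importance_fn


def _vip_scores(pls: PLSRegression, p: int) -> np.ndarray:
    """Variable importance in projection for a fitted PLS model.

    VIP_j = sqrt(p * sum_a ss_a (w_ja/||w_a||)^2 / sum_a ss_a) where
    ss_a = q_a^2 t_a' t_a is the outcome variance explained by component a.
    """
    W = pls.x_weights_  # p x A
    T = pls.x_scores_  # n x A
    Q = pls.y_loadings_  # 1 x A
    ss = (Q.ravel() ** 2) * np.einsum("ia,ia->a", T, T)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 > 0, wnorm2, 1.0)
    contrib = (W**2) / wnorm2  # p x A
    denom = ss.sum()
    if denom <= 0:
        return np.zeros(p)
    return np.sqrt(p * (contrib @ ss) / denom)


def _build_nsc(X, y, hp, seed):
    """Nearest shrunken centroids (soft-thresholded class centroids).

    Class centroids are shrunk toward the overall centroid by the threshold
    ``shrink`` in units of the standardized centroid difference; features
    whose differences shrink to zero for both classes drop out of the
    discriminant (the family's innate selection).
    """
    delta = float(hp.get("shrink", 1.0))
    classes = np.array([0, 1])
    n = X.shape[0]
    overall = X.mean(axis=0)
    cents, priors, mks = [], [], []
    within_ss = np.zeros(X.shape[1])
    for k in classes:
        Xk = X[y == k]
        cents.append(Xk.mean(axis=0))
        priors.append(len(Xk) / n)
        mks.append(math.sqrt(max(1.0 / len(Xk) - 1.0 / n, 1e-12)))
        within_ss += ((Xk - Xk.mean(axis=0)) ** 2).sum(axis=0)
    s = np.sqrt(within_ss / max(n - len(classes), 1))
    s0 = float(np.median(s))
    denom = s + s0
    d = np.array([(c - overall) / (m * denom) for c, m in zip(cents, mks)])
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunk_cents = np.array(
        [overall + m * denom * dk for dk, m in zip(d_shrunk, mks)]
    )
    log_priors = np.log(np.asarray(priors))

    def score_fn(Xnew):
        # discriminant: standardized squared distance to each shrunken centroid
        disc = np.stack(
            [
                ((Xnew - shrunk_cents[k]) ** 2 / denom**2).sum(axis=1) - 2.0 * log_priors[k]
                for k in range(2)
            ],
            axis=1,
        )
        post = np.exp(-0.5 * (disc - disc.min(axis=1, keepdims=True)))
        post /= post.sum(axis=1, keepdims=True)
        return post[:, 1]

    def importance_fn():
        return np.abs(d_shrunk).max(axis=0)

    return score_fn, importance_fn


def _build_random_forest(X, y, hp, seed):
    model = RandomForestClassifier(
        n_estimators=int(hp.get("n_estimators", 500)),
        max_features=hp.get("max_features", "sqrt"),
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return (lambda Xn: model.predict_proba(Xn)[:, 1]), (lambda: model.feature_importances_)


def _build_svm(X, y, hp, seed):
    kernel = hp.get("kernel", "linear")
    model = SVC(C=float(hp.get("C", 1.0)), kernel=kernel, gamma="scale", random_state=seed)
    model.fit(X, y)

    def score_fn(Xnew):
        # decision margin mapped through a sigmoid: monotone pseudo-probability
        return expit(model.decision_function(Xnew))

    if kernel == "linear":
        importance_fn = lambda: np.abs(model.coef_.ravel())
    else:
        rng = np.random.default_rng(seed)

        def importance_fn():
            return permutation_importance(
                lambda Xn: expit(model.decision_function(Xn)), X, y, rng, n_repeats=5
            )

    return score_fn, importance_fn


def _build_random_knn(X, y, hp, seed):
    """Ensemble of kNN classifiers on random feature subspaces.

    Each of ``n_learners`` base classifiers sees ceil(sqrt(p)) randomly
    drawn features. A learner's support weight is its leave-one-out
    training accuracy in excess of the no-information rate; a feature's
    importance is the mean support weight of the subspaces containing it.
    """
    k = int(hp.get("n_neighbors", 5))
    L = int(hp.get("n_learners", 150))
    rng = np.random.default_rng(seed)
    n, p = X.shape
    m = max(1, math.ceil(math.sqrt(p)))
    k = min(k, n - 1)
    baseline = max(y.mean(), 1 - y.mean())

    learners = []
    weight_sum = np.zeros(p)
    contain_count = np.zeros(p)
    for _ in range(L):
        subset = rng.choice(p, size=m, replace=False)
        Xs = X[:, subset]
        knn = KNeighborsClassifier(n_neighbors=k).fit(Xs, y)
        # leave-one-out training accuracy: drop each point's own vote
        neigh = knn.kneighbors(Xs, n_neighbors=min(k + 1, n), return_distance=False)
        votes = y[neigh[:, 1:]]
        pred = (votes.mean(axis=1) >= 0.5).astype(int)
        acc = float((pred == y).mean())
        w = max(0.0, acc - baseline)
        weight_sum[subset] += w
        contain_count[subset] += 1
        learners.append((subset, knn))

    def score_fn(Xnew):
        probs = np.zeros(Xnew.shape[0])
        for subset, knn in learners:
            probs += knn.predict_proba(Xnew[:, subset])[:, 1]
        return probs / len(learners)

    def importance_fn():
        with np.errstate(invalid="ignore"):
            imp = np.where(contain_count > 0, weight_sum / np.maximum(contain_count, 1), 0.0)
        return imp

    return score_fn, importance_fn


def _build_ada_boost(X, y, hp, seed):
    model = AdaBoostClassifier(
        n_estimators=int(hp.get("n_estimators", 50)),
        learning_rate=float(hp.get("learning_rate", 0.5)),
        random_state=seed,
    )
    model.fit(X, y)
    return (lambda Xn: model.predict_proba(Xn)[:, 1]), (lambda: model.feature_importances_)


def _build_lasso_logistic(X, y, hp, seed):
    model = LogisticRegression(
        l1_ratio=1.0, C=float(hp.get("C", 1.0)), solver="liblinear", max_iter=2000,
        random_state=seed,
    )
    model.fit(X, y)
    return (lambda Xn: model.predict_proba(Xn)[:, 1]), (lambda: np.abs(model.coef_.ravel()))


def _build_penalized_logistic(X, y, hp, seed):
    # elastic net, ridge-leaning mixing: distinct from the pure-L1 lasso family
    model = LogisticRegression(
        C=float(hp.get("C", 1.0)),
        l1_ratio=float(hp.get("l1_ratio", 0.1)),
        solver="saga",
        max_iter=5000,
        tol=1e-4,
        random_state=seed,
    )
    model.fit(X, y)
    return (lambda Xn: model.predict_proba(Xn)[:, 1]), (lambda: np.abs(model.coef_.ravel()))


_FAMILY_BUILDERS = {
    "pls_da": _build_pls_da,
    "nearest_shrunken_centroids": _build_nsc,
    "random_forest": _build_random_forest,
    "svm": _build_svm,
    "random_knn": _build_random_knn,
    "ada_boost_bag": _build_ada_boost,
    "lasso_logistic": _build_lasso_logistic,
    "penalized_logistic": _build_penalized_logistic,
}


def permutation_importance(
    score_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_repeats: int = 5,
) -> np.ndarray:
    """Model-agnostic importance: average-precision drop when a column is shuffled.

    Negative drops (the shuffled column scored no worse) are clipped to 0.
    """
    base = average_precision_score(y, score_fn(X))
    p = X.shape[1]
    imp = np.zeros(p)
    for j in range(p):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(base - average_precision_score(y, score_fn(Xp)))
        imp[j] = max(0.0, float(np.mean(drops)))
    return imp


# ----------------------------------------------------------------------
# importance extraction and selection


def importance_vector(fitted: FittedModel) -> ImportanceVector:
    """Innate importance vector plus selected mask per the spec's selection mode."""
    if len(fitted.feature_names) < 2:
        raise ValueError("importance extraction requires >= 2 features")
    imp = pd.Series(fitted.raw_importances(), index=fitted.feature_names, name="importance")
    if fitted.spec.selection_mode == "native":
        selected_ids = list(imp.index[imp.to_numpy() > 0])
    else:
        selected_ids = _top_n_ids(imp, fitted.spec.top_n)
    selected = pd.Series(imp.index.isin(selected_ids), index=imp.index, name="selected")
    return ImportanceVector(importances=imp, selected=selected, family_id=fitted.family_id)


def _top_n_ids(imp: pd.Series, n: int) -> list:
    """IDs of the N largest positive importances, ties broken by column order.

    Exact-zero importances are never selected: a model that assigned zero
    weight to a feature did not rank it at all.
    """
    vals = imp.to_numpy(dtype=float)
    order = sorted(range(len(vals)), key=lambda i: (-vals[i], i))
    out = [imp.index[i] for i in order[:n] if vals[i] > 0]
    return out


def top_selection(iv: ImportanceVector, rule) -> set:
    """Apply a selection rule to an importance vector.

    ``rule`` is ``"native"`` (intrinsic sparse support; only valid for
    families with one) or ``("top_n", N)`` / an integer N.
    """
    if rule == "native":
        if iv.family_id not in NATIVE_SPARSE_FAMILIES:
            raise ValueError(
                f"{iv.family_id} has no intrinsic sparse solution; native rule invalid"
            )
        return set(iv.importances.index[iv.importances.to_numpy() > 0])
    if isinstance(rule, tuple) and rule[0] == "top_n":
        n = int(rule[1])
    elif isinstance(rule, int):
        n = rule
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if n < 1:
        raise ValueError("top_n N must be >= 1")
    return set(_top_n_ids(iv.importances, n))
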