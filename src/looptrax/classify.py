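"""LOO-tuned supervised classification with a permutation null for accuracy.

The question is whether the E18.5 anatomical parameters carry enough signal
to predict an individual's embryonic looping class (or its trajectory
group).  The base learner is a random forest on one-hot encoded categorical
predictors, with Gini importances summed back per original variable.  The
hyperparameters "mtry" (variables sampled per split) and the number of trees
are tuned by leave-one-out cross-validation; when several grid points tie at
the best LOO accuracy, their importance vectors are averaged into a
consensus ranking.  Prediction accuracy is then measured by an independent
LOO pass (fresh seed), and its significance by a permutation null: at every
LOO fold the model's prediction is replaced by a label drawn uniformly from
the training fold's responses and scored against the true held-out label;
repeating over B replicates (default 5000) gives the accuracy distribution
of a signal-free predictor.  The empirical p is the fraction of null
replicates at or above the observed accuracy; the add-one variant
(1 + #) / (B + 1) is always reported alongside, since the plain fraction can
print as exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort_io import Cohort

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "PermutationNull",
    "design_matrix",
    "loo_tune",
    "consensus_importance",
    "permutation_test",
]


def _default_mtry_grid(p: int) -> tuple[int, ...]:
    return tuple(sorted({1, math.ceil(math.sqrt(p)), math.ceil(p / 2), p}))


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameter grid and seed for the bagged-tree base learner.

    ``mtry_grid`` counts original variables sampled per split (mapped
    proportionally onto the one-hot columns); ``trees_grid`` is the number
    of trees.  The defaults are recorded in output metadata — small cohorts
    do not support a finer grid.
    """

    mtry_grid: tuple[int, ...] = ()
    trees_grid: tuple[int, ...] = (100, 250, 500)
    seed: int = 0

    def resolved_mtry(self, p: int) -> tuple[int, ...]:
        grid = self.mtry_grid or _default_mtry_grid(p)
        if any(m < 1 or m > p for m in grid):
            raise ValueError(f"mtry grid {grid} outside [1, {p}]")
        return grid


@dataclass(frozen=True)
class CVResult:
    mtry: int
    n_trees: int
    predictions: tuple[str, ...]  # out-of-fold prediction per sample
    accuracy: float
    importances: pd.Series = field(repr=False)  # per original variable, full-data fit

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy outside [0, 1]")


@dataclass(frozen=True)
class PermutationNull:
    observed_accuracy: float
    null_accuracies: np.ndarray  # (B,)
    p_empirical: float  # #{null >= observed} / B
    p_add_one: float  # (1 + #{null >= observed}) / (B + 1)
    mean_null_accuracy: float
    B: int


def design_matrix(
    cohort: Cohort, predictors: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """One-hot encode the predictor columns; unknown codes become their own level.

    Returns the encoded frame plus the original-variable name of each
    encoded column (for summing importances back).
    """
    raw = pd.DataFrame({var: cohort.feature_column(var) for var in predictors})
    constant = [v for v in predictors if raw[v].nunique() < 2]
    if constant:
        import warnings

        warnings.warn(f"constant predictors dropped: {constant}", stacklevel=2)
        raw = raw.drop(columns=constant)
    encoded = pd.get_dummies(raw, prefix_sep="=")
    origins = [col.split("=", 1)[0] for col in encoded.columns]
    return encoded, origins


def _forest(
    mtry: int, n_trees: int, p_original: int, n_encoded: int, seed: int
) -> RandomForestClassifier:
    # mtry counts original variables; scale to the one-hot column count
    max_features = max(1, round(mtry / p_original * n_encoded))
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(max_features, n_encoded),
        random_state=seed,
        n_jobs=1,
    )


def _loo_predictions(
    X: np.ndarray, y: np.ndarray, mtry: int, n_trees: int, p_original: int, seed: int
) -> np.ndarray:
    n = len(y)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fold_seeds = rng.integers(0, 2**31, size=n)
    preds = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = _forest(mtry, n_trees, p_original, X.shape[1], int(fold_seeds[i]))
        clf.fit(X[mask], y[mask])
        preds[i] = clf.predict(X[i : i + 1])[0]
        mask[i] = True
    return preds


def loo_tune(
    cohort: Cohort,
    response: str,
    predictors: Sequence[str],
    spec: ClassifierSpec = ClassifierSpec(),
) -> tuple[list[CVResult], list[CVResult]]:
    """Grid search by leave-one-out cross-validation.

    Every record must have a known response (filter upstream).  Returns
    (tied best results, all grid results); ties at the maximum LOO accuracy
    are kept and propagated to :func:`consensus_importance`.
    """
    encoded, origins = design_matrix(cohort, predictors)
    resp_schema = cohort.schema[response] if response in cohort.schema else None
    y = np.array(cohort.feature_column(response), dtype=object)
    known = np.array(
        [resp_schema.is_known(v) if resp_schema else v not in ("unknown", "") for v in y]
    )
    if not known.all():
        raise ValueError(
            f"{int((~known).sum())} records have unknown response {response!r}; filter first"
        )
    n = len(y)
    if n < 3:
        raise ValueError("need at least three records for LOO-CV")
    if len(set(y)) < 2:
        raise ValueError("response has fewer than two levels")
    X = encoded.to_numpy(dtype=float)
    p_original = len(set(origins))

    results = []
    grid_seed_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    for mtry in spec.resolved_mtry(p_original):
        for n_trees in spec.trees_grid:
            point_seed = int(grid_seed_rng.integers(0, 2**31))
            preds = _loo_predictions(X, y, mtry, n_trees, p_original, point_seed)
            acc = float((preds == y).mean())
            full = _forest(mtry, n_trees, p_original, X.shape[1], point_seed)
            full.fit(X, y)
            imp = pd.Series(full.feature_importances_, index=origins).groupby(level=0).sum()
            results.append(
                CVResult(
                    mtry=mtry, n_trees=n_trees,
                    predictions=tuple(preds), accuracy=acc, importances=imp,
                )
            )
    best_acc = max(r.accuracy for r in results)
    best = [r for r in results if r.accuracy == best_acc]
    return best, results


def consensus_importance(tied_results: Sequence[CVResult]) -> pd.Series:
    """Average Gini importance across tied-best models, ranked descending.

    Ties in the averaged importance are broken stably by variable name.
    """
    if not tied_results:
        raise ValueError("need at least one result")
    stacked = pd.concat([r.importances for r in tied_results], axis=1)
    mean = stacked.mean(axis=1)
    return mean.sort_index().sort_values(ascending=False, kind="stable")


def permutation_test(
    cohort: Cohort,
    response: str,
    predictors: Sequence[str],
    mtry: int,
    n_trees: int,
    B: int = 5000,
    seed: int = 0,
) -> PermutationNull:
    """Permutation-calibrated significance of LOO prediction accuracy.

    The observed accuracy comes from an independent LOO pass at the given
    hyperparameters (its own seed stream).  Null replicate b replaces, at
    every fold, the model's prediction by a label drawn uniformly from the
    training fold's responses and scores it against the true held-out label
    — the held-out label itself is never among the candidates it is drawn
    from.  p = #{null >= observed} / B, with the add-one variant alongside.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    encoded, origins = design_matrix(cohort, predictors)
    y = np.array(cohort.feature_column(response), dtype=object)
    X = encoded.to_numpy(dtype=float)
    n = len(y)
    p_original = len(set(origins))

    obs_seed, null_seed = (
        int(s) for s in np.random.default_rng(np.random.SeedSequence([seed, 11])).integers(0, 2**31, 2)
    )
    preds = _loo_predictions(X, y, mtry, n_trees, p_original, obs_seed)
    observed = float((preds == y).mean())

    # P(random training-fold label matches the truth) per fold: the count of
    # the held-out label among the other n-1 responses, over n-1
    labels, counts = np.unique(y, return_counts=True)
    count_of = dict(zip(labels, counts))
    p_hit = np.array([(count_of[yi] - 1) / (n - 1) for yi in y])

    rng = np.random.default_rng(np.random.SeedSequence(null_seed))
    null = (rng.random((B, n)) < p_hit[None, :]).mean(axis=1)
    hits = int((null >= observed - 1e-12).sum())
    return PermutationNull(
        observed_accuracy=observed,
        null_accuracies=null,
        p_empirical=hits / B,
        p_add_one=(1 + hits) / (B + 1),
        mean_null_accuracy=float(null.mean()),
        B=B,
    )
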