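"""Classifier families, inner-CV grid search and the positivity baseline.

The three default families and their hyperparameter grids mirror the
benchmark setup this package evaluates:

====================  =====================================================
family                grid
====================  =====================================================
knn                   n_neighbors: [25, 75, 125]
logistic_regression   C: [0.0001, 1, 10] x penalty: [l1, l2]
random_forest         n_estimators: [100, 200] x min_samples_leaf:
                      [1, 10, 50] x max_samples: [0.75, 1.0]
====================  =====================================================

Logistic regression uses the liblinear solver, which supports both l1 and
l2 penalties.  The inner-CV selection criterion defaults to MCC for
consistency with the evaluation metric; accuracy is available via
``criterion="accuracy"``.

The positivity baseline (PositivityBaseline) predicts a pair's label purely
from the training positivity of its member proteins — the learned fraction
of positive interactions each protein participates in.  It carries no
biological signal and exists to expose how much of a classifier's score is
explained by per-protein label bias.  In ``single_item`` mode only the
first-listed protein's positivity is used, so the baseline emits one
constant prediction per first protein; ``pair_mean`` averages both
endpoints' positivities.  Proteins unseen in training fall back to the
global training positivity, and exact-threshold ties predict negative.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, matthews_corrcoef
from sklearn.neighbors import KNeighborsClassifier

from ppibias.data_model import InteractionDataset, POSITIVE
from ppibias.metrics import PredictionRecord, PredictionSet
from ppibias.splits import Fold, FoldPlan

FAMILIES = ("knn", "logistic_regression", "random_forest")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [25, 75, 125]},
    "logistic_regression": {"C": [0.0001, 1, 10], "penalty": ["l1", "l2"]},
    "random_forest": {
        "n_estimators": [100, 200],
        "min_samples_leaf": [1, 10, 50],
        "max_samples": [0.75, 1.0],
    },
}


class GridSearchError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """A classifier family plus its hyperparameter grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.grid:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.family])
        if any(not values for values in self.grid.values()):
            raise ValueError("every grid parameter needs at least one value")

    def points(self) -> list[dict]:
        """All grid points, in grid order (first parameter varies slowest)."""
        names = list(self.grid)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.grid[n] for n in names))
        ]


def make_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate a scikit-learn classifier for one grid point."""
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "logistic_regression":
        params = dict(params)
        # the public grid speaks in penalties; newer sklearn wants l1_ratio
        penalty = params.pop("penalty", "l2")
        return LogisticRegression(
            solver="liblinear",
            l1_ratio={"l1": 1.0, "l2": 0.0}[penalty],
            max_iter=1000,
            random_state=seed,
            **params,
        )
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown family {family!r}")


_CRITERIA = {"mcc": matthews_corrcoef, "accuracy": accuracy_score}


def _infeasible(family: str, params: dict, n_train: int) -> bool:
    # e.g. more KNN neighbours than training rows
    return family == "knn" and params.get("n_neighbors", 0) > n_train


@dataclass
class GridSearchResult:
    best_params: dict
    best_score: float
    table: list[dict]  # one row per grid point: params, per-fold scores, mean


def grid_search(
    spec: GridSpec,
    inner_folds: Sequence[Fold],
    X: np.ndarray,
    y: np.ndarray,
    *,
    criterion: str = "mcc",
    seed: int = 0,
) -> GridSearchResult:
    """Score every grid point by mean criterion over the inner validation
    folds and return the argmax (ties broken by grid order, first wins).

    Inner folds whose training rows contain a single class are skipped with
    a warning; if every fold is degenerate the search fails.  Grid points
    infeasible on some fold (e.g. ``n_neighbors`` exceeding the fold's
    training size) skip that fold likewise.
    """
    score_fn = _CRITERIA[criterion]
    usable_folds = []
    for fold in inner_folds:
        train = np.asarray(fold.train_idx, dtype=int)
        if len(np.unique(y[train])) < 2:
            warnings.warn(
                "inner fold skipped: training labels are single-class", stacklevel=2
            )
            continue
        usable_folds.append(fold)
    if not usable_folds:
        raise GridSearchError("all inner folds have single-class training labels")

    table: list[dict] = []
    best: tuple[float, dict] | None = None
    for params in spec.points():
        fold_scores: list[float] = []
        for fold in usable_folds:
            train = np.asarray(fold.train_idx, dtype=int)
            valid = np.asarray(fold.valid_idx, dtype=int)
            if _infeasible(spec.family, params, len(train)):
                warnings.warn(
                    f"grid point {params} infeasible on a fold with "
                    f"{len(train)} training rows; fold skipped",
                    stacklevel=2,
                )
                continue
            est = make_estimator(spec.family, params, seed=seed)
            est.fit(X[train], y[train])
            fold_scores.append(float(score_fn(y[valid], est.predict(X[valid]))))
        mean = float(np.mean(fold_scores)) if fold_scores else float("-inf")
        table.append({"params": params, "fold_scores": fold_scores, "mean": mean})
        if fold_scores and (best is None or mean > best[0]):
            best = (mean, params)
    if best is None:
        raise GridSearchError("no feasible grid point could be scored")
    return GridSearchResult(best_params=best[1], best_score=best[0], table=table)


def fit_predict_outer(
    plan: FoldPlan,
    spec: GridSpec,
    X: np.ndarray,
    y: np.ndarray,
    ds: InteractionDataset,
    *,
    criterion: str = "mcc",
    seed: int = 0,
) -> PredictionSet:
    """Nested-CV evaluation: per outer fold, grid-search on its inner folds,
    refit the winner on the full outer training set and predict the outer
    validation set.  All validation predictions are pooled, tagged by fold.
    """
    if len(ds) != len(y):
        raise ValueError("dataset and label vector lengths differ")
    records: list[PredictionRecord] = []
    chosen: list[dict] = []
    for fold_id, (fold, inner) in enumerate(zip(plan.outer, plan.inner)):
        result = grid_search(spec, inner, X, y, criterion=criterion, seed=seed)
        train = np.asarray(fold.train_idx, dtype=int)
        valid = np.asarray(fold.valid_idx, dtype=int)
        est = make_estimator(spec.family, result.best_params, seed=seed)
        est.fit(X[train], y[train])
        predictions = est.predict(X[valid])
        for i, pred in zip(valid, predictions):
            records.append(
                PredictionRecord(ds.interactions[int(i)], int(pred), fold_id)
            )
        chosen.append({"fold": fold_id, "params": result.best_params, "inner_score": result.best_score})
    return PredictionSet(records, meta={"family": spec.family, "chosen": chosen, "seed": seed})


# ---------------------------------------------------------------------------
# positivity baseline
# ---------------------------------------------------------------------------

@dataclass
class PositivityBaseline:
    positivity: dict[str, float]
    global_rate: float
    mode: str = "single_item"
    threshold: float = 0.5

    def score(self, protein_a: str, protein_b: str) -> float:
        pa = self.positivity.get(protein_a, self.global_rate)
        if self.mode == "single_item":
            return pa
        pb = self.positivity.get(protein_b, self.global_rate)
        return (pa + pb) / 2.0


def baseline_fit(
    train: InteractionDataset | Sequence, mode: str = "single_item", threshold: float = 0.5
) -> PositivityBaseline:
    """Learn each training protein's positivity and the global rate."""
    if mode not in ("single_item", "pair_mean"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    interactions = train.interactions if isinstance(train, InteractionDataset) else list(train)
    pos: dict[str, int] = {}
    tot: dict[str, int] = {}
    n_pos = 0
    for it in interactions:
        for p in it.proteins:
            tot[p] = tot.get(p, 0) + 1
            if it.label == POSITIVE:
                pos[p] = pos.get(p, 0) + 1
        n_pos += it.label == POSITIVE
    positivity = {p: pos.get(p, 0) / tot[p] for p in tot}
    global_rate = n_pos / len(interactions) if interactions else 0.5
    return PositivityBaseline(positivity, global_rate, mode=mode, threshold=threshold)


def baseline_predict(b: PositivityBaseline, pair: tuple[str, str]) -> int:
    """Positive iff the (mode-dependent) positivity strictly exceeds the
    threshold; exact ties predict negative."""
    return 1 if b.score(*pair) > b.threshold else 0


def baseline_fit_predict_outer(
    plan: FoldPlan, ds: InteractionDataset, mode: str = "single_item"
) -> PredictionSet:
    """Evaluate the positivity baseline under a fold plan, pooling outer
    validation predictions like :func:`fit_predict_outer`."""
    records: list[PredictionRecord] = []
    for fold_id, fold in enumerate(plan.outer):
        model = baseline_fit([ds.interactions[i] for i in fold.train_idx], mode=mode)
        for i in fold.valid_idx:
            it = ds.interactions[i]
            pred = baseline_predict(model, (it.protein_a, it.protein_b))
            records.append(PredictionRecord(it, pred, fold_id))
    return PredictionSet(records, meta={"family": f"positivity_baseline[{mode}]"})
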