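"""Gradient-boosted-tree surrogate of A450 with nested-CV evaluation.

The surrogate regresses per-medium mean blank-subtracted A450 at a chosen
timepoint on the fold vector.  Hyperparameters (learning rate, tree depth)
are chosen by grid search under inner k-fold cross-validation minimizing
MAE, with a deterministic tie-break (lowest learning rate, then lowest
depth).  Accuracy is reported by 5x5 nested cross-validation — the outer
folds never touch the inner selection — with MAE, R² and RMSE per outer
fold.  Feature importance is impurity-reduction (Gini) importance from the
fitted ensembles, averaged over the outer-CV models and over independent
re-runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.metrics import mean_absolute_error, r2_score

from .dataset import Dataset
from .design import MediumCombination, derive_seed

__all__ = [
    "HyperParamGrid",
    "SurrogateModel",
    "CVReport",
    "ImportanceReport",
    "enumerate_hyperparameter_grid",
    "fit_surrogate",
    "predict_response",
    "nested_cv_evaluate",
    "feature_importance",
    "kfold_indices",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class HyperParamGrid:
    """Hyperparameter grid for the tree ensemble.

    The full-scale default enumerates learning rates 0.001 + 0.005*j while
    <= 0.5 (100 values) crossed with depths 2..5 at 300 boosting stages —
    400 settings.  ``reduced()`` is a 4-setting desk-scale grid for tests
    and simulation studies.
    """

    learning_rates: tuple[float, ...] = ()
    max_depths: tuple[int, ...] = (2, 3, 4, 5)
    n_estimators: int = 300

    def __post_init__(self):
        lrs = self.learning_rates or self._default_lrs()
        if any(lr <= 0 for lr in lrs):
            raise ValueError("learning rates must be positive")
        if any(d < 1 for d in self.max_depths):
            raise ValueError("max_depth must be >= 1")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        object.__setattr__(self, "learning_rates", tuple(lrs))
        object.__setattr__(self, "max_depths", tuple(self.max_depths))

    @staticmethod
    def _default_lrs(start: float = 0.001, stop: float = 0.5, step: float = 0.005):
        out = []
        j = 0
        while True:
            lr = start + step * j
            if lr > stop + 1e-12:
                break
            out.append(round(lr, 10))
            j += 1
        return tuple(out)

    @classmethod
    def full_scale(cls) -> "HyperParamGrid":
        return cls()

    @classmethod
    def reduced(cls, n_estimators: int = 100) -> "HyperParamGrid":
        return cls(learning_rates=(0.01, 0.1), max_depths=(2, 3), n_estimators=n_estimators)

    def __len__(self) -> int:
        return len(self.learning_rates) * len(self.max_depths)


def enumerate_hyperparameter_grid(grid: HyperParamGrid) -> list[dict]:
    """Full Cartesian enumeration, learning rate ascending then depth ascending."""
    return [
        {"learning_rate": lr, "max_depth": d, "n_estimators": grid.n_estimators}
        for lr in grid.learning_rates
        for d in grid.max_depths
    ]


@dataclass
class SurrogateModel:
    """Fitted tree ensemble plus the provenance needed to reuse it."""

    estimator: GradientBoostingRegressor
    params: dict
    target_timepoint: float
    rng_seed: int
    n_train: int
    feature_names: list[str]
    format_version: int = MODEL_FORMAT_VERSION

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))


@dataclass
class CVReport:
    """Outer-fold metrics of a nested cross-validation."""

    mae: np.ndarray
    r2: np.ndarray
    rmse: np.ndarray
    chosen_params: list[dict]
    fold_test_indices: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.mae))

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse))

    def summary(self) -> dict:
        return {
            "mae_mean": self.mean_mae,
            "mae_sd": float(np.std(self.mae, ddof=1)) if len(self.mae) > 1 else 0.0,
            "r2_mean": self.mean_r2,
            "r2_sd": float(np.std(self.r2, ddof=1)) if len(self.r2) > 1 else 0.0,
            "rmse_mean": self.mean_rmse,
            "rmse_sd": float(np.std(self.rmse, ddof=1)) if len(self.rmse) > 1 else 0.0,
        }


@dataclass
class ImportanceReport:
    """Per-component impurity-reduction importance, mean +- sd over replicates."""

    components: list[str]
    mean: np.ndarray
    sd: np.ndarray
    per_replicate: np.ndarray  # (n_replicates, n_components), each row sums to 1
    n_replicates: int
    normalized: bool = True

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        order = np.argsort(self.mean)[::-1][:k]
        return [(self.components[i], float(self.mean[i])) for i in order]


# ---------------------------------------------------------------------------
# CV machinery
# ---------------------------------------------------------------------------

def kfold_indices(n: int, k: int, rng_seed: int) -> list[np.ndarray]:
    """Seeded-shuffle contiguous-block k-fold assignment; sizes differ by <= 1."""
    if k < 2 or n < k:
        raise ValueError(f"cannot split {n} points into {k} folds")
    perm = np.random.default_rng(rng_seed).permutation(n)
    return [np.sort(block) for block in np.array_split(perm, k)]


def _fit_gbr(X, y, params: dict, rng_seed: int) -> GradientBoostingRegressor:
    est = GradientBoostingRegressor(random_state=rng_seed, **params)
    est.fit(X, y)
    return est


def _grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperParamGrid,
    n_folds: int,
    rng_seed: int,
) -> dict:
    """Inner-CV grid search minimizing mean MAE; first minimum wins the tie
    (enumeration order is learning rate ascending, then depth ascending)."""
    folds = kfold_indices(len(y), n_folds, rng_seed)
    settings = enumerate_hyperparameter_grid(grid)
    best_params, best_score = None, np.inf
    for params in settings:
        maes = []
        for test_idx in folds:
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            est = _fit_gbr(X[train_mask], y[train_mask], params, rng_seed)
            maes.append(mean_absolute_error(y[test_idx], est.predict(X[test_idx])))
        score = float(np.mean(maes))
        if score < best_score - 1e-15:
            best_score, best_params = score, params
    return best_params


def fit_surrogate(
    dataset: Dataset,
    target_timepoint: float,
    grid: Optional[HyperParamGrid] = None,
    n_inner_folds: int = 5,
    rng_seed: int = 0,
) -> SurrogateModel:
    """Grid-search hyperparameters by inner CV, then refit on the full dataset.

    Features are fold vectors; the target is the per-medium mean
    blank-subtracted A450 at ``target_timepoint``.
    """
    grid = grid or HyperParamGrid()
    if len(dataset) < n_inner_folds:
        raise ValueError(
            f"dataset has {len(dataset)} combinations; need >= {n_inner_folds} for inner CV"
        )
    X = dataset.features()
    y = dataset.mean_a450(target_timepoint).to_numpy()
    params = _grid_search(X, y, grid, n_inner_folds, rng_seed)
    est = _fit_gbr(X, y, params, rng_seed)
    return SurrogateModel(
        estimator=est,
        params=params,
        target_timepoint=target_timepoint,
        rng_seed=rng_seed,
        n_train=len(y),
        feature_names=dataset.space.names,
    )


def predict_response(
    model: SurrogateModel, combos: Sequence[MediumCombination]
) -> np.ndarray:
    """Predicted A450 for each combination, order-preserving."""
    if len(combos) == 0:
        return np.empty(0)
    X = np.array([c.folds for c in combos], dtype=float)
    if X.shape[1] != len(model.feature_names):
        raise ValueError("combination length does not match the model's feature order")
    return model.predict(X)


def nested_cv_evaluate(
    dataset: Dataset,
    target_timepoint: float,
    grid: Optional[HyperParamGrid] = None,
    rng_seed: int = 0,
    n_outer_folds: int = 5,
    n_inner_folds: int = 5,
) -> CVReport:
    """Nested cross-validation: outer folds score models whose hyperparameters
    were chosen by inner grid search on the outer-training data only."""
    grid = grid or HyperParamGrid()
    if len(dataset) < max(10, n_outer_folds * 2):
        raise ValueError(f"dataset too small ({len(dataset)}) for nested CV")
    X = dataset.features()
    y = dataset.mean_a450(target_timepoint).to_numpy()
    outer = kfold_indices(len(y), n_outer_folds, rng_seed)
    mae, r2, rmse, chosen = [], [], [], []
    for fold_i, test_idx in enumerate(outer):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        inner_seed = derive_seed(rng_seed, "inner", fold_i)
        params = _grid_search(Xtr, ytr, grid, n_inner_folds, inner_seed)
        est = _fit_gbr(Xtr, ytr, params, inner_seed)
        pred = est.predict(X[test_idx])
        obs = y[test_idx]
        mae.append(mean_absolute_error(obs, pred))
        r2.append(r2_score(obs, pred))
        rmse.append(float(np.sqrt(np.mean((pred - obs) ** 2))))
        chosen.append(params)
    return CVReport(
        mae=np.array(mae),
        r2=np.array(r2),
        rmse=np.array(rmse),
        chosen_params=chosen,
        fold_test_indices=outer,
    )


def feature_importance(
    dataset: Dataset,
    target_timepoint: float,
    grid: Optional[HyperParamGrid] = None,
    n_replicates: int = 5,
    rng_seed: int = 0,
    n_outer_folds: int = 5,
    n_inner_folds: int = 5,
) -> ImportanceReport:
    """Impurity-reduction importance averaged over outer-CV models and replicates.

    Each replicate re-runs the outer-CV fit procedure with a derived seed;
    importances of the (up to) five outer-fold models are averaged within
    the replicate and normalized to sum to 1; the report carries the mean
    and sd over replicates.
    """
    grid = grid or HyperParamGrid()
    X = dataset.features()
    y = dataset.mean_a450(target_timepoint).to_numpy()
    if len(y) < n_outer_folds * 2:
        raise ValueError("dataset too small for outer CV importance")
    rows = []
    for rep in range(n_replicates):
        seed = derive_seed(rng_seed, "importance", rep)
        outer = kfold_indices(len(y), n_outer_folds, seed)
        imps = []
        for fold_i, test_idx in enumerate(outer):
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            inner_seed = derive_seed(seed, "inner", fold_i)
            params = _grid_search(X[train_mask], y[train_mask], grid, n_inner_folds, inner_seed)
            est = _fit_gbr(X[train_mask], y[train_mask], params, inner_seed)
            imps.append(est.feature_importances_)
        rep_mean = np.mean(imps, axis=0)
        total = rep_mean.sum()
        rows.append(rep_mean / total if total > 0 else rep_mean)
    per_rep = np.array(rows)
    return ImportanceReport(
        components=dataset.space.names,
        mean=per_rep.mean(axis=0),
        sd=per_rep.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(per_rep.shape[1]),
        per_replicate=per_rep,
        n_replicates=n_replicates,
    )


def save_model(model: SurrogateModel, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> SurrogateModel:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {blob.get('format_version')!r}")
    return blob["model"]
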