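"""Closed-loop campaign driver: fit -> predict -> select -> measure -> append.

Each round fits the surrogate on all data so far, predicts A450 over a
freshly sampled candidate pool, greedily takes the top-k unseen media,
measures them (through the synthetic oracle or a lab-in-the-loop callback)
at every timepoint, and appends the results to the training set.  The
campaign objective is the readout at 168 h in *regular* mode or at 96 h in
*time-saving* mode.  A seeded random-selection baseline with the identical
budget serves as the control for the loop's efficacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .culture_sim import OracleParams, build_dataset
from .dataset import Dataset
from .design import DesignSpace, MediumCombination, derive_seed, generate_initial_design, sample_candidates
from .surrogate import (
    CVReport,
    HyperParamGrid,
    ImportanceReport,
    SurrogateModel,
    feature_importance,
    fit_surrogate,
    nested_cv_evaluate,
    predict_response,
)

__all__ = [
    "CampaignConfig",
    "RoundResult",
    "CampaignResult",
    "select_batch",
    "run_round",
    "run_campaign",
    "run_random_baseline",
]

_MODE_OBJECTIVE = {"regular": 168.0, "time_saving": 96.0}
FINAL_TIMEPOINT = 168.0


@dataclass
class CampaignConfig:
    """Campaign settings.

    ``batch_sizes`` overrides ``batch_size`` per round (e.g. ``[19, 18, 19,
    18]`` replicates alternating wet-lab batches).  ``max_changes`` bounds
    how many components a candidate may alter from baseline (default 4,
    ~1e7 media; ``None`` samples the unrestricted grid).  ``evaluate_cv``
    controls whether a nested-CV accuracy report is computed after each
    augmentation (expensive; switch off for large simulation sweeps).
    """

    mode: str = "regular"
    objective_timepoint: Optional[float] = None
    n_rounds: int = 4
    batch_size: int = 19
    batch_sizes: Optional[Sequence[int]] = None
    candidate_cap: int = 10_000_000
    max_changes: Optional[int] = 4
    n_replicates: int = 3
    seed: int = 0
    grid: HyperParamGrid = field(default_factory=HyperParamGrid)
    n_inner_folds: int = 5
    evaluate_cv: bool = True
    compute_importance: bool = True
    importance_replicates: int = 5
    include_baseline: bool = True
    n_best: int = 10

    def __post_init__(self):
        if self.mode not in _MODE_OBJECTIVE:
            raise ValueError(f"mode must be one of {sorted(_MODE_OBJECTIVE)}")
        if self.objective_timepoint is None:
            self.objective_timepoint = _MODE_OBJECTIVE[self.mode]
        if self.objective_timepoint != _MODE_OBJECTIVE[self.mode]:
            raise ValueError(
                f"mode {self.mode!r} requires objective {_MODE_OBJECTIVE[self.mode]} h"
            )
        if self.n_rounds < 1 or self.batch_size < 1:
            raise ValueError("n_rounds and batch_size must be >= 1")
        if self.batch_sizes is not None and len(self.batch_sizes) != self.n_rounds:
            raise ValueError("batch_sizes must have one entry per round")

    def round_batch_size(self, round_index: int) -> int:
        if self.batch_sizes is not None:
            return int(self.batch_sizes[round_index - 1])
        return self.batch_size


@dataclass
class RoundResult:
    round_index: int
    batch: list[MediumCombination]
    predicted: np.ndarray
    observed_objective: np.ndarray
    cv_report: Optional[CVReport]
    best_so_far_objective: float
    best_so_far_final: float
    pool_size: int


@dataclass
class CampaignResult:
    config: CampaignConfig
    initial_size: int
    rounds: list[RoundResult]
    dataset: Dataset
    importance: Optional[ImportanceReport]
    best_media: list[tuple[str, float]]  # (id, observed objective mean), descending

    @property
    def best_trajectory(self) -> list[float]:
        """Best observed objective after the initial design and each round."""
        ds = self.dataset
        obj = self.config.objective_timepoint
        best = [float(ds.mean_a450(obj, ds.ids_in_round("initial")).max())]
        for r in self.rounds:
            best.append(r.best_so_far_objective)
        return best


def select_batch(
    model: SurrogateModel,
    pool: Sequence[MediumCombination],
    k: int,
    tested: Optional[set] = None,
) -> list[MediumCombination]:
    """Top-k pool members by predicted A450, excluding already-tested media.

    Ties in the prediction are broken by ascending lexicographic fold
    vector, which makes selection deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tested = tested or set()
    eligible = [c for c in pool if c.key() not in tested]
    if not eligible:
        raise ValueError("empty eligible pool")
    preds = predict_response(model, eligible)
    order = sorted(range(len(eligible)), key=lambda i: (-preds[i], eligible[i].key()))
    return [eligible[i] for i in order[:k]]


ObserveFn = Callable[[Sequence[MediumCombination], str], Dataset]


def _observe(
    oracle: Optional[OracleParams],
    observe_fn: Optional[ObserveFn],
    batch: Sequence[MediumCombination],
    round_label: str,
    config: CampaignConfig,
    seed: int,
) -> Dataset:
    if observe_fn is not None:
        return observe_fn(batch, round_label)
    if oracle is None:
        raise ValueError("either an oracle or an observe_fn must be provided")
    return build_dataset(
        oracle,
        batch,
        n_replicates=config.n_replicates,
        rng_seed=seed,
        round_label=round_label,
        mode=config.mode,
    )


def run_round(
    dataset: Dataset,
    space: DesignSpace,
    oracle: Optional[OracleParams],
    config: CampaignConfig,
    round_index: int,
    observe_fn: Optional[ObserveFn] = None,
    select: str = "model",
) -> tuple[RoundResult, Dataset]:
    """One fit/predict/select/measure/append round; returns the augmented dataset."""
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    seed_r = (config.seed ^ round_index) & 0x7FFFFFFF
    tested = dataset.keys()
    pool = sample_candidates(
        space,
        config.candidate_cap,
        rng_seed=seed_r,
        exclude=dataset.combos(),
        max_changes=config.max_changes,
    )
    k = config.round_batch_size(round_index)

    if select == "model":
        model = fit_surrogate(
            dataset,
            config.objective_timepoint,
            grid=config.grid,
            n_inner_folds=config.n_inner_folds,
            rng_seed=seed_r,
        )
        batch = select_batch(model, pool, k, tested)
        predicted = predict_response(model, batch)
    elif select == "random":
        rng = np.random.default_rng(derive_seed(seed_r, "random-batch"))
        eligible = [c for c in pool if c.key() not in tested]
        if not eligible:
            raise ValueError("empty eligible pool")
        idx = rng.choice(len(eligible), size=min(k, len(eligible)), replace=False)
        batch = [eligible[i] for i in sorted(idx)]
        predicted = np.full(len(batch), np.nan)
    else:
        raise ValueError("select must be 'model' or 'random'")

    label = f"round{round_index}"
    batch = [c.with_id(f"{label}_{i:02d}") for i, c in enumerate(batch, start=1)]
    new = _observe(oracle, observe_fn, batch, label, config, derive_seed(seed_r, "observe"))
    augmented = dataset.copy()
    augmented.extend(new)

    cv = None
    if config.evaluate_cv:
        cv = nested_cv_evaluate(
            augmented,
            config.objective_timepoint,
            grid=config.grid,
            rng_seed=seed_r,
            n_inner_folds=config.n_inner_folds,
        )
    result = RoundResult(
        round_index=round_index,
        batch=batch,
        predicted=predicted,
        observed_objective=new.mean_a450(config.objective_timepoint).to_numpy(),
        cv_report=cv,
        best_so_far_objective=float(augmented.mean_a450(config.objective_timepoint).max()),
        best_so_far_final=float(augmented.mean_a450(FINAL_TIMEPOINT).max()),
        pool_size=len(pool),
    )
    return result, augmented


def _run_loop(
    space: DesignSpace,
    oracle: Optional[OracleParams],
    config: CampaignConfig,
    select: str,
    initial_dataset: Optional[Dataset],
    observe_fn: Optional[ObserveFn],
) -> CampaignResult:
    if initial_dataset is not None:
        dataset = initial_dataset.copy()
    else:
        design = generate_initial_design(space, include_baseline=config.include_baseline)
        dataset = _observe(
            oracle, observe_fn, design, "initial", config, derive_seed(config.seed, "initial")
        )
    initial_size = len(dataset)
    rounds: list[RoundResult] = []
    for round_index in range(1, config.n_rounds + 1):
        result, dataset = run_round(
            dataset, space, oracle, config, round_index, observe_fn=observe_fn, select=select
        )
        rounds.append(result)

    importance = None
    if config.compute_importance:
        importance = feature_importance(
            dataset,
            config.objective_timepoint,
            grid=config.grid,
            n_replicates=config.importance_replicates,
            rng_seed=config.seed,
            n_inner_folds=config.n_inner_folds,
        )
    means = dataset.mean_a450(config.objective_timepoint).sort_values(ascending=False)
    best = [(i, float(v)) for i, v in means.head(config.n_best).items()]
    return CampaignResult(
        config=config,
        initial_size=initial_size,
        rounds=rounds,
        dataset=dataset,
        importance=importance,
        best_media=best,
    )


def run_campaign(
    space: DesignSpace,
    oracle: Optional[OracleParams],
    config: CampaignConfig,
    initial_dataset: Optional[Dataset] = None,
    observe_fn: Optional[ObserveFn] = None,
) -> CampaignResult:
    """Full active-learning campaign (OFAT initial design unless one is given)."""
    return _run_loop(space, oracle, config, "model", initial_dataset, observe_fn)


def run_random_baseline(
    space: DesignSpace,
    oracle: Optional[OracleParams],
    config: CampaignConfig,
    initial_dataset: Optional[Dataset] = None,
    observe_fn: Optional[ObserveFn] = None,
) -> CampaignResult:
    """Identical loop and budget, but batches drawn uniformly from the pool.

    No surrogate is fitted (its predictions would be ignored), so round
    results carry NaN predictions.
    """
    return _run_loop(space, oracle, config, "random", initial_dataset, observe_fn)
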