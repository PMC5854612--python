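"""Parameter tuning and cross-dataset evaluation protocol.

Detector parameters are tuned per dataset with a grid search over the
permutation-normalized composite score (the *training score*). To control
for overfitting on one dataset's quirks, the optimal parameters of one
dataset are then applied to another and rescored (the *test score*) — an
analogue of cross-validation across expression compendia. Scores from many
(dataset, module definition) combinations are combined with a weighted mean
in which every organism and every module definition carries equal total
weight. Dataset perturbation (sample subsampling, added noise) supports
sensitivity analyses.

Detectors attach through a plain callable contract:
``detector(expr: ExpressionMatrix, params: dict) -> ModuleSet``; the same
inputs must give the same output (seed via a ``seed`` param if stochastic).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ModuleSet
from .null_models import normalized_scores
from .scores import restrict_observed

__all__ = [
    "ParamGrid",
    "TuneResult",
    "grid_search",
    "transfer_test",
    "aggregate_scores",
    "perturb_dataset",
    "score_observed",
]


class ParamGrid:
    """Named parameters with ordered candidate values; iterates the cartesian
    product in declaration order."""

    def __init__(self, params: Mapping):
        if not params:
            raise ValueError("parameter grid must be non-empty")
        self.params = {str(k): list(v) for k, v in params.items()}
        if any(not v for v in self.params.values()):
            raise ValueError("every grid parameter needs at least one candidate value")

    def points(self) -> list:
        names = list(self.params)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.params[n] for n in names))
        ]

    def __len__(self) -> int:
        n = 1
        for v in self.params.values():
            n *= len(v)
        return n

    def __contains__(self, point: Mapping) -> bool:
        return dict(point) in self.points()


@dataclass(frozen=True)
class TuneResult:
    grid_scores: tuple  # tuple of (params dict, composite score)
    best_params: dict
    training_score: float
    dataset_id: str = ""
    definition_id: str = ""
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset_id,
            "definition": self.definition_id,
            "seed": self.seed,
            "training_score": self.training_score,
            "best_params": dict(self.best_params),
            "grid": [{"params": dict(p), "score": s} for p, s in self.grid_scores],
        }


def score_observed(
    observed: ModuleSet,
    known: ModuleSet,
    universe: Iterable,
    n_perm: int,
    seed: int,
    min_size: int = 5,
) -> float:
    """Normalized composite of an observed module set against a gold standard.

    Observed modules are first restricted to the known-module gene union and
    size-filtered; an empty restriction scores 0.
    """
    restricted = restrict_observed(observed, known.genes, min_size=min_size)
    if len(restricted) == 0:
        return 0.0
    report = normalized_scores(known, restricted, universe, n_perm=n_perm, seed=seed)
    return report.composite


def grid_search(
    detector: Callable,
    grid: ParamGrid,
    expr: ExpressionMatrix,
    known: ModuleSet,
    universe: Iterable,
    n_perm: int = 100,
    seed: int = 0,
    dataset_id: str = "",
    definition_id: str = "",
    min_size: int = 5,
) -> TuneResult:
    """Run the detector at every grid point and keep the point with the best
    normalized composite score (ties: first in grid order). A detector
    failure at a grid point scores 0 with a warning instead of aborting."""
    results = []
    for params in grid.points():
        try:
            observed = detector(expr, params)
            score = score_observed(observed, known, universe, n_perm, seed, min_size=min_size)
        except Exception as exc:  # noqa: BLE001 - a failing grid point is data, not fatal
            warnings.warn(f"detector failed at {params}: {exc}; scoring 0", stacklevel=2)
            score = 0.0
        results.append((params, float(score)))
    best_params, training = max(results, key=lambda item: item[1])
    # max() keeps the first maximizer in grid order
    first_best = next(p for p, s in results if s == training)
    return TuneResult(
        grid_scores=tuple(results),
        best_params=first_best,
        training_score=training,
        dataset_id=dataset_id,
        definition_id=definition_id,
        seed=seed,
    )


def transfer_test(
    source: TuneResult,
    detector: Callable,
    grid: ParamGrid,
    target_expr: ExpressionMatrix,
    target_known: ModuleSet,
    universe: Iterable,
    n_perm: int = 100,
    seed: int = 0,
    min_size: int = 5,
    source_is_real: bool | None = None,
    target_is_real: bool | None = None,
) -> float:
    """Test score: rescore the detector on a target dataset using the best
    parameters tuned on a source dataset.

    When realness tags are supplied, transfer between synthetic and real
    datasets is refused — optimal parameters differ systematically between
    the two, so mixing them corrupts the protocol.
    """
    if source.best_params not in grid:
        raise ValueError("source best_params are not a point of the given grid")
    if source_is_real is not None and target_is_real is not None and source_is_real != target_is_real:
        raise ValueError("refusing transfer between real and synthetic datasets")
    observed = detector(target_expr, source.best_params)
    return score_observed(observed, target_known, universe, n_perm, seed, min_size=min_size)


def aggregate_scores(scores) -> float:
    """Weighted mean of per-(dataset, definition) scores in which every
    organism and every module definition has equal total influence.

    ``scores`` is a DataFrame or iterable of mappings with columns/keys
    dataset, organism, definition, score. Each row is weighted by
    1 / (n_organisms * n_datasets_in_its_organism * n_definitions).
    """
    table = scores if isinstance(scores, pd.DataFrame) else pd.DataFrame(list(scores))
    if table.empty:
        raise ValueError("score table is empty")
    required = {"dataset", "organism", "definition", "score"}
    missing = required - set(table.columns)
    if missing or table[list(required - {"score"})].isna().any().any():
        raise ValueError(f"every row needs labels {sorted(required)}; missing {sorted(missing) or 'values'}")
    n_org = table["organism"].nunique()
    n_def = table["definition"].nunique()
    datasets_per_org = table.groupby("organism")["dataset"].nunique()
    weights = table["organism"].map(lambda o: 1.0 / (n_org * datasets_per_org[o] * n_def))
    return float(np.average(table["score"], weights=weights))


def perturb_dataset(
    expr: ExpressionMatrix,
    sample_fraction: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Subsample samples (without replacement) and add i.i.d. Gaussian noise;
    the instrument behind sample-size and noise sensitivity analyses."""
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(expr.samples)
    k = round(sample_fraction * n)
    if k < 2:
        raise ValueError(f"subsampling to {k} sample(s); need at least 2")
    chosen = np.sort(rng.choice(n, size=k, replace=False))
    frame = expr.frame.iloc[:, chosen].copy()
    if noise_sd > 0:
        frame += rng.normal(0.0, noise_sd, size=frame.shape)
    return ExpressionMatrix(frame)
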