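"""Repeated random-split evaluation and success-rate statistics.

The evaluation protocol draws a fresh stratified 70/30 train/test split for
each of (by default) 100 repetitions, trains a classifier on the training
part and scores the held-out part; the mean of the per-repetition success
rates is the reported figure. This deliberately differs from fixed-partition
cross-validation: with very small clusters a fixed partition biases the SR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import EmptyInputError, ShapeError, StratificationError

#: fit(features, labels, seed) -> object with .predict(features)
ClassifierFactory = Callable[[np.ndarray, np.ndarray, int], object]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SplitPlan:
    """Frozen train/test index sets for every repetition.

    Splits are stratified per cluster: each cluster contributes
    ``round(train_fraction * size)`` training samples (round half up, kept
    within 1..size-1 so both parts stay nonempty) in every repetition; only
    the membership is redrawn.
    """

    repetitions: int
    train_fraction: float
    seed: int
    splits: tuple[tuple[np.ndarray, np.ndarray], ...]

    @classmethod
    def from_labels(
        cls,
        labels: Sequence,
        repetitions: int = 100,
        train_fraction: float = 0.7,
        seed: int = 0,
    ) -> "SplitPlan":
        labels = np.asarray(labels)
        if labels.size == 0:
            raise EmptyInputError("no samples to split")
        if not 0.0 < train_fraction < 1.0:
            raise StratificationError(f"train_fraction must be in (0, 1), got {train_fraction}")
        clusters = [np.nonzero(labels == value)[0] for value in np.unique(labels)]
        for indices in clusters:
            if indices.size < 2:
                raise StratificationError(
                    "every cluster needs >= 2 members to yield nonempty train and test sets"
                )
        rng = np.random.default_rng(seed)
        splits = []
        for _ in range(repetitions):
            train_parts, test_parts = [], []
            for indices in clusters:
                n_train = _round_half_up(train_fraction * indices.size)
                n_train = min(max(n_train, 1), indices.size - 1)
                shuffled = rng.permutation(indices)
                train_parts.append(shuffled[:n_train])
                test_parts.append(shuffled[n_train:])
            splits.append(
                (np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts)))
            )
        return cls(
            repetitions=repetitions,
            train_fraction=train_fraction,
            seed=seed,
            splits=tuple(splits),
        )


@dataclass
class EvaluationResult:
    task: str
    sr_values: np.ndarray
    config: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def mean_sr(self) -> float:
        return float(np.mean(self.sr_values))

    @property
    def std_sr(self) -> float:
        return float(np.std(self.sr_values, ddof=1)) if self.sr_values.size > 1 else 0.0

    @property
    def stderr_sr(self) -> float:
        return self.std_sr / math.sqrt(self.sr_values.size)


def success_rate(predicted: Sequence, truth: Sequence) -> float:
    """Fraction of samples assigned their correct cluster."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size == 0 or truth.size == 0:
        raise EmptyInputError("success_rate needs nonempty label sequences")
    if predicted.shape != truth.shape:
        raise ShapeError(f"label shapes differ: {predicted.shape} vs {truth.shape}")
    return float(np.mean(predicted == truth))


def repeated_split_evaluation(
    features: np.ndarray,
    labels: Sequence,
    factory: ClassifierFactory,
    plan: SplitPlan | None = None,
    task: str = "",
    seed: int = 0,
) -> EvaluationResult:
    """Mean held-out SR over repeated stratified random splits.

    ``factory(train_X, train_y, seed)`` must return a fitted object exposing
    ``predict``; it is called once per repetition with a per-repetition seed
    derived from the plan seed, so the whole evaluation is reproducible.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ShapeError("features and labels disagree on the number of samples")
    if np.unique(labels).size < 2:
        raise StratificationError("evaluation needs >= 2 clusters")
    if plan is None:
        plan = SplitPlan.from_labels(labels, seed=seed)
    sr_values = np.empty(plan.repetitions)
    flags = []
    for rep, (train_idx, test_idx) in enumerate(plan.splits):
        model = factory(features[train_idx], labels[train_idx], plan.seed + rep)
        predicted = model.predict(features[test_idx])
        sr_values[rep] = success_rate(predicted, labels[test_idx])
        if getattr(model, "accepted", True) is False:
            flags.append({"repetition": rep, "flag": "not_accepted"})
    return EvaluationResult(
        task=task,
        sr_values=sr_values,
        config={
            "repetitions": plan.repetitions,
            "train_fraction": plan.train_fraction,
            "seed": plan.seed,
        },
        flags=flags,
    )


def average_error(sr_values: Sequence[float]) -> float:
    """Mean of (1 - SR) across classification tasks."""
    sr_values = np.asarray(sr_values, dtype=float)
    if sr_values.size == 0:
        raise EmptyInputError("average_error needs at least one SR value")
    if np.any((sr_values < 0) | (sr_values > 1)):
        raise ShapeError("SR values must lie in [0, 1]")
    return float(np.mean(1.0 - sr_values))


def combine_best(sr_a: Sequence[float], sr_b: Sequence[float]) -> np.ndarray:
    """Elementwise best SR of two aligned per-task lists."""
    sr_a = np.asarray(sr_a, dtype=float)
    sr_b = np.asarray(sr_b, dtype=float)
    if sr_a.shape != sr_b.shape:
        raise ShapeError(f"per-task SR lists differ in shape: {sr_a.shape} vs {sr_b.shape}")
    return np.maximum(sr_a, sr_b)
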