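"""Wrapper cost function for feature-subset search.

A candidate subset is scored by training a k-nearest-neighbor classifier
(Euclidean distance, majority vote, K = 5) on a fixed stratified 80/20
holdout split of the feature table and combining the test accuracy with a
subset-size penalty:

    J = alpha * (1 - Accuracy) + beta * n_selected / D,

with the conventional weights alpha = 0.99 and beta = 0.01, so J lies in
[0, 1] and is dominated by the accuracy term. Continuous search positions
in [0, 1]^D are mapped to subsets by thresholding at 0.5 (strict ">").
An empty subset is scored at the worst cost (1.0) rather than repaired.

The k-NN is implemented directly in numpy for bit-exact reproducibility:
neighbors at equal distance are taken in trial-index order and vote ties
resolve to the smallest class label. Within one optimizer run the split is
fixed, so the cost landscape is static and convergence curves comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, ParameterError, SplitError
from .features import FeatureTable

__all__ = [
    "CostSpec",
    "FeatureMask",
    "SplitFixture",
    "binarize",
    "wrapper_cost",
    "make_split",
    "knn_accuracy",
    "evaluate_cost",
    "exhaustive_oracle",
    "CostEvaluator",
]


@dataclass(frozen=True)
class CostSpec:
    """Parameters of the wrapper cost and its holdout split."""

    alpha: float = 0.99
    beta: float = 0.01
    k: int = 5
    holdout_fraction: float = 0.2
    split_seed: int = 0
    binarize_threshold: float = 0.5
    empty_mask_cost: float = 1.0
    standardize: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.holdout_fraction < 1):
            raise ParameterError("holdout_fraction must be in (0, 1)")
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if not (0 < self.binarize_threshold < 1):
            raise ParameterError("binarize_threshold must be in (0, 1)")
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be >= 0")


@dataclass(frozen=True)
class FeatureMask:
    """Binary feature-inclusion vector."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ParameterError("mask bits must be 0 or 1")

    @property
    def n_selected(self) -> int:
        return int(sum(self.bits))

    @property
    def d(self) -> int:
        return len(self.bits)

    def as_bool(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=bool)

    @classmethod
    def all_ones(cls, d: int) -> "FeatureMask":
        return cls(bits=(1,) * d)

    @classmethod
    def from_indices(cls, indices: set[int] | list[int], d: int) -> "FeatureMask":
        idx = set(indices)
        return cls(bits=tuple(1 if i in idx else 0 for i in range(d)))

    def to_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "FeatureMask":
        return cls(bits=tuple(int(c) for c in s))


@dataclass(frozen=True)
class SplitFixture:
    """Stratified train/test trial indices, fixed for a whole search run."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]


def wrapper_cost(accuracy: float, n_selected: int, d: int,
                 spec: CostSpec = CostSpec()) -> float:
    """J = alpha (1 - accuracy) + beta n_selected / d (non-empty subsets)."""
    return spec.alpha * (1.0 - accuracy) + spec.beta * n_selected / d


def binarize(position: np.ndarray, threshold: float = 0.5) -> FeatureMask:
    """Map a continuous position to a mask: bit d = 1 iff position[d] > threshold."""
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise DataError("position contains non-finite values")
    return FeatureMask(bits=tuple(int(b) for b in (position > threshold)))


def _encode_labels(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[l] for l in labels], dtype=np.intp), classes


def make_split(table: FeatureTable, spec: CostSpec,
               seed: int | None = None) -> SplitFixture:
    """Seeded stratified holdout split; deterministic given (table, spec, seed).

    Per class, ``round(holdout_fraction * n_class)`` trials go to the test
    set. Class label order and within-class trial order are fixed, so the
    same seed always yields the same index sets.
    """
    if seed is None:
        seed = spec.split_seed
    y, classes = _encode_labels(table.labels)
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for ci in range(len(classes)):
        members = np.flatnonzero(y == ci)
        if members.size < 2:
            raise SplitError(
                f"class {classes[ci]!r} has {members.size} trial(s); need >= 2"
            )
        n_test = int(round(spec.holdout_fraction * members.size))
        n_test = min(max(n_test, 1), members.size - 1)
        perm = rng.permutation(members.size)
        test.extend(int(members[i]) for i in perm[:n_test])
        train.extend(int(members[i]) for i in perm[n_test:])
    return SplitFixture(train_indices=tuple(sorted(train)),
                        test_indices=tuple(sorted(test)))


class CostEvaluator:
    """Precomputed per-feature distance tensor for fast repeated mask scoring.

    For one (table, split, spec) the squared per-feature differences between
    every test and train trial are computed once; the distance for any mask
    is then a masked sum, which makes the ~10^5 cost evaluations of a full
    metaheuristic comparison cheap.
    """

    def __init__(self, table: FeatureTable, split: SplitFixture, spec: CostSpec):
        y, self.classes = _encode_labels(table.labels)
        tr = np.asarray(split.train_indices, dtype=np.intp)
        te = np.asarray(split.test_indices, dtype=np.intp)
        if set(tr) & set(te):
            raise SplitError("train and test indices overlap")
        if spec.k > tr.size:
            raise ParameterError(f"k={spec.k} exceeds train size {tr.size}")
        x_train = table.values[tr]
        x_test = table.values[te]
        if spec.standardize:
            mu = x_train.mean(axis=0)
            sd = x_train.std(axis=0)
            sd[sd == 0] = 1.0
            x_train = (x_train - mu) / sd
            x_test = (x_test - mu) / sd
        self.y_train = y[tr]
        self.y_test = y[te]
        self.spec = spec
        self.d = table.n_features
        # (D, n_test, n_train) squared per-feature differences
        self._diff2 = (x_test[:, :, None].transpose(1, 0, 2)
                       - x_train.T[:, None, :]) ** 2

    def accuracy(self, mask: FeatureMask) -> float:
        if mask.n_selected == 0:
            raise ParameterError("empty mask has no k-NN accuracy")
        dist2 = self._diff2[mask.as_bool()].sum(axis=0)
        correct = 0
        k = self.spec.k
        n_classes = len(self.classes)
        for row, truth in zip(dist2, self.y_test):
            order = np.argsort(row, kind="stable")  # distance ties -> index order
            votes = np.bincount(self.y_train[order[:k]], minlength=n_classes)
            if votes.argmax() == truth:  # vote ties -> smallest class label
                correct += 1
        return correct / len(self.y_test)

    def cost(self, mask: FeatureMask) -> tuple[float, float, int]:
        """Return (J, accuracy, n_selected); empty masks score empty_mask_cost."""
        n_sel = mask.n_selected
        if n_sel == 0:
            return self.spec.empty_mask_cost, 0.0, 0
        acc = self.accuracy(mask)
        return float(wrapper_cost(acc, n_sel, mask.d, self.spec)), float(acc), n_sel

    def cost_of_position(self, position: np.ndarray) -> tuple[float, float, int, FeatureMask]:
        mask = binarize(position, self.spec.binarize_threshold)
        j, acc, n_sel = self.cost(mask)
        return j, acc, n_sel, mask


def knn_accuracy(table: FeatureTable, mask: FeatureMask,
                 split: SplitFixture, k: int = 5) -> float:
    """Holdout k-NN accuracy using only the masked feature columns."""
    spec = CostSpec(k=k)
    return CostEvaluator(table, split, spec).accuracy(mask)


def evaluate_cost(
    position_or_mask: np.ndarray | FeatureMask,
    table: FeatureTable,
    split: SplitFixture,
    spec: CostSpec,
) -> tuple[float, float, int]:
    """One-shot wrapper cost evaluation: returns (J, accuracy, n_selected)."""
    evaluator = CostEvaluator(table, split, spec)
    if isinstance(position_or_mask, FeatureMask):
        mask = position_or_mask
    else:
        mask = binarize(np.asarray(position_or_mask), spec.binarize_threshold)
    return evaluator.cost(mask)


def exhaustive_oracle(
    table: FeatureTable,
    split: SplitFixture,
    spec: CostSpec,
    d_max: int = 12,
) -> tuple[FeatureMask, float]:
    """Enumerate every non-empty mask and return the true cost minimum.

    Intended as ground truth for optimizer testing on small tables. Ties
    resolve to fewer selected features, then to lexicographically smaller
    bit tuples. Refuses tables wider than ``d_max`` (2^D blow-up).
    """
    d = table.n_features
    if d > d_max:
        raise ParameterError(f"D={d} exceeds the combinatorial guard d_max={d_max}")
    evaluator = CostEvaluator(table, split, spec)
    best: tuple[float, int, tuple[int, ...]] | None = None
    for bits in itertools.product((0, 1), repeat=d):
        if not any(bits):
            continue
        mask = FeatureMask(bits=bits)
        j, _, n_sel = evaluator.cost(mask)
        key = (j, n_sel, bits)
        if best is None or key < best:
            best = key
    assert best is not None
    return FeatureMask(bits=best[2]), best[0]
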