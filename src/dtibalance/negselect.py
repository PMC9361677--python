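"""Reliable-negative selection from the unlabeled pair pool.

A one-class SVM (RBF kernel, small nu) is fit on the known-positive pairs
of each feature set; its signed decision function scores every unlabeled
pair (>= 0 inside the positive region, < 0 outside). Pairs that fall
outside the positive region under the configured consensus rule across the
four feature sets are ranked by their combined standardized distance, and
the k most outlying become PREDICTED_NEGATIVE — yielding a balanced
positive/negative training set without random negative sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import OneClassSVM

from dtibalance.descriptors import PairFeatureMatrix
from dtibalance.io_formats import InteractionSet, Label
from dtibalance.metrics import MetricsReport

FEATURE_SET_IDS = ("FS1", "FS2", "FS3", "FS4")


@dataclass(frozen=True)
class OneClassModelSpec:
    kernel: str = "rbf"
    nu: float = 0.01
    gamma: str | float = "scale"

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")
        if not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")


@dataclass
class FittedOneClass:
    model: OneClassSVM
    spec: OneClassModelSpec
    n_features: int
    fold_diagnostics: list[MetricsReport]


@dataclass
class DistanceTable:
    """Signed distances of candidate pairs to one positive hyperplane."""

    feature_set_id: str
    pair_keys: list[tuple[str, str]]
    distances: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pair_keys) != self.distances.shape[0]:
            raise ValueError("one distance per pair required")
        if self.distances.size and not np.isfinite(self.distances).all():
            raise ValueError("distances must be finite")


@dataclass
class NegativeSelection:
    selected: list[tuple[str, str]]
    per_set_distance: np.ndarray  # qualifying pairs x feature sets
    combined_score: np.ndarray
    k_requested: int
    shortfall: bool = False  # fewer qualifiers than requested
    qualifying: list[tuple[str, str]] = field(default_factory=list)


def fit_one_class(
    positive_features: PairFeatureMatrix,
    spec: OneClassModelSpec = OneClassModelSpec(),
    folds: int = 10,
    seed: int = 0,
) -> FittedOneClass:
    """Fit a one-class SVM on positive pairs with k-fold self-diagnostics.

    Each fold trains on the remaining positives and scores the held-out
    positives as inliers/outliers; fold precision/recall/F1/accuracy
    measure how well held-out positives are recognized as inliers. The
    returned model is refit on all positives.
    """
    x = np.asarray(positive_features.matrix, dtype=float)
    if x.shape[0] < folds:
        raise ValueError(
            f"need at least {folds} positive rows for {folds}-fold diagnostics, "
            f"got {x.shape[0]}"
        )
    if not np.isfinite(x).all():
        raise ValueError("positive feature matrix contains non-finite values")

    diagnostics: list[MetricsReport] = []
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(x):
        fold_model = OneClassSVM(kernel=spec.kernel, nu=spec.nu, gamma=spec.gamma)
        fold_model.fit(x[train_idx])
        inlier = fold_model.predict(x[test_idx]) == 1
        tp = int(inlier.sum())
        fn = int((~inlier).sum())
        recall = tp / (tp + fn)
        precision = 1.0 if tp else 0.0  # held-out set is all-positive: fp == 0
        f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
        diagnostics.append(
            MetricsReport(accuracy=recall, precision=precision, recall=recall, f1=f1)
        )

    model = OneClassSVM(kernel=spec.kernel, nu=spec.nu, gamma=spec.gamma)
    model.fit(x)
    return FittedOneClass(model, spec, x.shape[1], diagnostics)


def signed_distances(
    fitted: FittedOneClass, candidates: PairFeatureMatrix
) -> DistanceTable:
    """Signed distance of each candidate to the positive hyperplane."""
    x = np.asarray(candidates.matrix, dtype=float)
    if x.shape[0] == 0:
        return DistanceTable(candidates.feature_set_id, [], np.empty(0))
    if x.shape[1] != fitted.n_features:
        raise ValueError(
            f"candidate width {x.shape[1]} != training width {fitted.n_features}"
        )
    dist = fitted.model.decision_function(x)
    return DistanceTable(candidates.feature_set_id, list(candidates.pair_keys), dist)


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def select_negatives(
    tables: Mapping[str, DistanceTable] | Sequence[DistanceTable],
    k: int,
    consensus: str = "ALL_SETS",
) -> NegativeSelection:
    """Rank consensus outliers and keep the k most outlying pairs.

    Per-set distances are z-scored before averaging because the feature
    sets have incomparable widths (50-1424 columns) and hence distance
    scales. ``consensus`` picks which candidates qualify:

    - ``ALL_SETS``: distance < 0 in every feature set (default),
    - ``ANY_SET``: distance < 0 in at least one set,
    - ``MEAN_SCORE``: mean standardized distance < 0.

    Ties in the combined score break by lexicographic pair key. When fewer
    than ``k`` candidates qualify, all of them are returned and
    ``shortfall`` is flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if consensus not in ("ALL_SETS", "ANY_SET", "MEAN_SCORE"):
        raise ValueError(f"unknown consensus rule {consensus!r}")
    if isinstance(tables, Mapping):
        table_list = [tables[fs] for fs in sorted(tables)]
    else:
        table_list = sorted(tables, key=lambda t: t.feature_set_id)
    if not table_list:
        raise ValueError("no distance tables given")

    keys = table_list[0].pair_keys
    key_set = set(keys)
    for t in table_list[1:]:
        if set(t.pair_keys) != key_set:
            raise ValueError(
                f"pair coverage of {t.feature_set_id} differs from "
                f"{table_list[0].feature_set_id}"
            )

    # Align all tables to the first table's pair order.
    raw = np.empty((len(keys), len(table_list)))
    for col, t in enumerate(table_list):
        if t.pair_keys == keys:
            raw[:, col] = t.distances
        else:
            pos = {key: i for i, key in enumerate(t.pair_keys)}
            raw[:, col] = t.distances[[pos[key] for key in keys]]

    z = np.column_stack([_zscore(raw[:, c]) for c in range(raw.shape[1])])
    combined = z.mean(axis=1)

    if consensus == "ALL_SETS":
        qualifies = (raw < 0).all(axis=1)
    elif consensus == "ANY_SET":
        qualifies = (raw < 0).any(axis=1)
    else:
        qualifies = combined < 0

    q_idx = np.nonzero(qualifies)[0]
    order = sorted(q_idx, key=lambda i: (combined[i], keys[i]))
    shortfall = len(order) < k
    if shortfall:
        warnings.warn(
            f"only {len(order)} qualifying candidates for k={k}", stacklevel=2
        )
    chosen = order[:k]
    return NegativeSelection(
        selected=[keys[i] for i in chosen],
        per_set_distance=raw[chosen],
        combined_score=combined[chosen],
        k_requested=k,
        shortfall=shortfall,
        qualifying=[keys[i] for i in order],
    )


def build_balanced_set(
    positives: InteractionSet, selection: NegativeSelection
) -> InteractionSet:
    """POSITIVE pairs plus the selected PREDICTED_NEGATIVE pairs."""
    pos_keys = set(positives.keys())
    overlap = pos_keys & set(selection.selected)
    if overlap:
        raise ValueError(
            f"selection overlaps positives: {sorted(overlap)[:3]} ..."
        )
    pairs = [(d, p, Label.POSITIVE) for d, p in positives.keys()]
    pairs += [(d, p, Label.PREDICTED_NEGATIVE) for d, p in selection.selected]
    if len(selection.selected) < len(pos_keys):
        warnings.warn(
            f"unbalanced labeled set: {len(pos_keys)} positives vs "
            f"{len(selection.selected)} predicted negatives",
            stacklevel=2,
        )
    return InteractionSet(pairs)
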