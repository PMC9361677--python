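"""Class-balancing baselines: random undersampling and SMOTE.

SMOTE is implemented from the published algorithm directly (synthetic
minority rows interpolated toward one of the k nearest minority
neighbors); an external resampling library is deliberately not required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass(frozen=True)
class BalanceSpec:
    method: str  # RANDOM_UNDERSAMPLE | SMOTE
    seed: int = 0
    smote_k: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("RANDOM_UNDERSAMPLE", "SMOTE"):
            raise ValueError(f"unknown balance method {self.method!r}")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


def _class_split(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    idx0 = np.nonzero(labels == 0)[0]
    idx1 = np.nonzero(labels == 1)[0]
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both classes must be non-empty")
    return idx0, idx1


def random_undersample(
    features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the majority class down (without replacement) to minority size."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    idx0, idx1 = _class_split(labels)
    minority, majority = (idx0, idx1) if idx0.size <= idx1.size else (idx1, idx0)
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=minority.size, replace=False)
    keep = np.sort(np.concatenate([minority, kept_majority]))
    return features[keep], labels[keep]


def smote_oversample(
    features: np.ndarray, labels: np.ndarray, spec: BalanceSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample the minority class to majority size with SMOTE.

    Each synthetic row is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1) and
    x_nn one of the ``smote_k`` nearest minority neighbors of x_i. Returns
    (features, labels, synthetic_flag) with equal class counts; the flag
    marks interpolated rows.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    idx0, idx1 = _class_split(labels)
    minority, majority = (idx0, idx1) if idx0.size <= idx1.size else (idx1, idx0)
    if minority.size <= spec.smote_k:
        raise ValueError(
            f"minority class has {minority.size} rows <= smote_k={spec.smote_k}; "
            "use a smaller smote_k"
        )
    n_needed = majority.size - minority.size
    if n_needed == 0:
        return features, labels, np.zeros(labels.size, dtype=bool)

    minority_x = features[minority]
    minority_label = int(labels[minority[0]])
    # +1 because each point is its own nearest neighbor.
    nn = NearestNeighbors(n_neighbors=spec.smote_k + 1).fit(minority_x)
    neighbor_idx = nn.kneighbors(minority_x, return_distance=False)[:, 1:]

    rng = np.random.default_rng(spec.seed)
    base = rng.integers(0, minority.size, size=n_needed)
    picks = neighbor_idx[base, rng.integers(0, spec.smote_k, size=n_needed)]
    u = rng.uniform(0.0, 1.0, size=n_needed)[:, None]
    synthetic = minority_x[base] + u * (minority_x[picks] - minority_x[base])

    out_x = np.vstack([features, synthetic])
    out_y = np.concatenate([labels, np.full(n_needed, minority_label)])
    flag = np.concatenate(
        [np.zeros(labels.size, dtype=bool), np.ones(n_needed, dtype=bool)]
    )
    return out_x, out_y, flag


def apply_balance(
    features: np.ndarray, labels: np.ndarray, spec: BalanceSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch on the configured method; used inside CV training folds."""
    if spec.method == "RANDOM_UNDERSAMPLE":
        return random_undersample(features, labels, seed=spec.seed)
    x, y, _ = smote_oversample(features, labels, spec)
    return x, y
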