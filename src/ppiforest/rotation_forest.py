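"""Rotation Forest ensemble classifier, built from scratch.

Each of the L member trees sees the training data through its own sparse
rotation: the feature set is randomly split into K disjoint subsets; for
every subset, PCA is estimated on a bootstrap resample (75% of the
training set by default) of just those columns, and the full set of
per-subset principal-axis coefficient vectors is placed as a diagonal
block of an n x n rotation matrix (rearranged back to original feature
order).  The tree itself is trained on the FULL training set rotated by
that matrix — resampling only perturbs the PCA estimate, which is what
creates diversity among otherwise-deterministic trees.  Prediction
averages the member trees' class-probability outputs and takes the
highest-confidence class.

The base learner is a standard CART decision tree (Gini impurity,
unlimited depth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "RoFConfig",
    "RotationSpec",
    "RotationForestModel",
    "partition_features",
    "build_rotation",
    "fit",
    "predict_confidence",
    "predict",
    "save_rof_model",
    "load_rof_model",
]


@dataclass(frozen=True)
class RoFConfig:
    """Rotation Forest hyperparameters.

    n_subsets
        K, the number of disjoint feature subsets per tree.
    n_trees
        L, the ensemble size.
    sample_fraction
        Fraction of training samples drawn (with replacement) for each
        per-subset PCA estimate.
    bootstrap
        If False, PCA is estimated on the full training set (no
        resampling); used for oracle comparisons.
    seed
        Seed of all randomness (partitions, resamples, tree tie-breaks).
    """

    n_subsets: int = 10
    n_trees: int = 35
    sample_fraction: float = 0.75
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


@dataclass
class RotationSpec:
    """One tree's feature partition and its n x n block rotation matrix."""

    partition: list[np.ndarray]
    rotation: np.ndarray


@dataclass
class RotationForestModel:
    config: RoFConfig
    members: list[tuple[RotationSpec, DecisionTreeClassifier]]
    classes: np.ndarray
    n_features: int = field(default=0)


def partition_features(
    n_features: int, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Randomly split feature indices 0..n-1 into K disjoint covering
    subsets.  A random permutation is cut into K contiguous chunks; when K
    does not divide n, the first (n mod K) chunks get one extra index."""
    if not 1 <= k <= n_features:
        raise ValueError(f"K must be in [1, {n_features}], got {k}")
    perm = rng.permutation(n_features)
    base, extra = divmod(n_features, k)
    sizes = [base + 1 if j < extra else base for j in range(k)]
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(perm[start : start + s]))
        start += s
    return out


def _block_pca(x_block: np.ndarray) -> np.ndarray:
    """All principal-axis coefficient vectors of a column block (columns of
    the returned matrix, orthonormal).  A zero-variance block yields the
    identity."""
    c = x_block.shape[1]
    xc = x_block - x_block.mean(axis=0)
    cov = (xc.T @ xc) / max(x_block.shape[0] - 1, 1)
    if np.allclose(cov, 0.0):
        warnings.warn("zero-variance feature subset: identity block", stacklevel=2)
        return np.eye(c)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    for j in range(c):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return evecs


def build_rotation(
    x_train: np.ndarray,
    labels: np.ndarray,
    partition: list[np.ndarray],
    sample_fraction: float,
    rng: np.random.Generator,
    bootstrap: bool = True,
) -> RotationSpec:
    """Build one sparse rotation matrix from per-subset PCA coefficients.

    For each feature subset, a bootstrap resample of ceil(fraction * N)
    training rows (with replacement) is drawn and PCA is run on the
    resampled columns; all coefficient vectors are kept as the subset's
    diagonal block.  Rows/columns are placed back at the original feature
    indices, so ``x @ rotation`` maps data in original feature order into
    the rotated space.
    """
    x_train = np.asarray(x_train, dtype=float)
    n_samples, n_features = x_train.shape
    if n_samples < 2:
        raise ValueError("need at least 2 training samples")
    rotation = np.zeros((n_features, n_features))
    for idx in partition:
        if len(idx) == 0:
            raise RuntimeError("empty feature subset in partition")
        if bootstrap:
            size = int(np.ceil(sample_fraction * n_samples))
            rows = rng.integers(0, n_samples, size=size)
            sample = x_train[np.ix_(rows, idx)]
        else:
            sample = x_train[:, idx]
        block = _block_pca(sample)
        rotation[np.ix_(idx, idx)] = block
    return RotationSpec(partition=partition, rotation=rotation)


def fit(x: np.ndarray, y: np.ndarray, config: RoFConfig | None = None) -> RotationForestModel:
    """Train a Rotation Forest: L independent (partition, rotation, tree)
    members, each tree trained on the full rotated training set.
    Deterministic given ``config.seed``."""
    config = config or RoFConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n_samples, n_features = x.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if config.n_subsets > n_features:
        raise ValueError(
            f"K={config.n_subsets} exceeds feature count {n_features}"
        )
    rng = np.random.default_rng(config.seed)
    members: list[tuple[RotationSpec, DecisionTreeClassifier]] = []
    for _ in range(config.n_trees):
        partition = partition_features(n_features, config.n_subsets, rng)
        spec = build_rotation(
            x, y, partition, config.sample_fraction, rng, bootstrap=config.bootstrap
        )
        tree = DecisionTreeClassifier(
            criterion="gini",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(x @ spec.rotation, y)
        members.append((spec, tree))
    return RotationForestModel(
        config=config, members=members, classes=classes, n_features=n_features
    )


def predict_confidence(model: RotationForestModel, x: np.ndarray) -> np.ndarray:
    """Average class-probability matrix m_j(x) = (1/L) sum_i d_ij(x G_i)
    over the L member trees.  Rows sum to 1."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {x.shape[1]}"
        )
    n_classes = model.classes.size
    conf = np.zeros((x.shape[0], n_classes))
    for spec, tree in model.members:
        proba = tree.predict_proba(x @ spec.rotation)
        # Map the tree's class order onto the model's class order.
        cols = np.searchsorted(model.classes, tree.classes_)
        conf[:, cols] += proba
    return conf / len(model.members)


def predict(model: RotationForestModel, x: np.ndarray) -> np.ndarray:
    """Highest-confidence class per sample; ties break toward the lower
    class index."""
    conf = predict_confidence(model, x)
    return model.classes[np.argmax(conf, axis=1)]


def save_rof_model(model: RotationForestModel, path) -> None:
    joblib.dump(model, path)


def load_rof_model(path) -> RotationForestModel:
    return joblib.load(path)
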