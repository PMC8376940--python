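"""Evaluation protocol: confusion-matrix metrics, ROC/AUC, stratified
five-fold cross-validation of the full pipeline, and the K x L grid
search over the Rotation Forest hyperparameters.

Metrics, with positive class = interacting (label 1):

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Pre = TP / (TP + FP)
    Sen = TP / (TP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TN+FP)(TP+FN))

A zero denominator makes the affected metric 0 and is flagged.  AUC is
the Mann-Whitney probability that a random interacting pair scores above
a random non-interacting one (ties count one half).

Cross-validation is leakage-free: within each fold the OLPP embedding is
fitted on descriptors of proteins appearing in training pairs only, and
held-out pairs are embedded with that fitted model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import olpp as olpp_mod
from . import rotation_forest as rof_mod
from .descriptor import make_pair_features
from .olpp import OLPPConfig
from .rotation_forest import RoFConfig

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvaluationReport",
    "confusion",
    "metrics",
    "roc_auc",
    "cross_validate",
    "grid_search",
]

METRIC_NAMES = ("acc", "pre", "sen", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in (("tp", self.tp), ("tn", self.tn), ("fp", self.fp), ("fn", self.fn)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("empty confusion table")


@dataclass(frozen=True)
class Metrics:
    acc: float
    pre: float
    sen: float
    mcc: float
    degenerate: tuple[str, ...] = ()


@dataclass
class EvaluationReport:
    """Per-fold and aggregate metrics of one cross-validated run."""

    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    std: dict[str, float]  # sample std over folds (ddof=1)
    config: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def __str__(self) -> str:
        lines = ["fold  " + "  ".join(f"{m.upper():>7}" for m in METRIC_NAMES)]
        for i, fold in enumerate(self.per_fold):
            lines.append(
                f"{i + 1:>4}  " + "  ".join(f"{fold[m]:7.4f}" for m in METRIC_NAMES)
            )
        lines.append(
            "mean  " + "  ".join(f"{self.mean[m]:7.4f}" for m in METRIC_NAMES)
        )
        lines.append(
            " std  " + "  ".join(f"{self.std[m]:7.4f}" for m in METRIC_NAMES)
        )
        return "\n".join(lines)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """2 x 2 confusion counts with positive class 1."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision, sensitivity and Matthews correlation from a
    confusion table.  Any metric with a zero denominator is reported as 0
    and listed in ``degenerate``."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    degenerate: list[str] = []

    acc = (tp + tn) / (tp + tn + fp + fn)
    if tp + fp > 0:
        pre = tp / (tp + fp)
    else:
        pre = 0.0
        degenerate.append("pre")
    if tp + fn > 0:
        sen = tp / (tp + fn)
    else:
        sen = 0.0
        degenerate.append("sen")
    denom = (tp + fp) * (tn + fn) * (tn + fp) * (tp + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc = 0.0
        degenerate.append("mcc")
    return Metrics(acc=acc, pre=pre, sen=sen, mcc=mcc, degenerate=tuple(degenerate))


def roc_auc(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, float]:
    """ROC points and AUC.

    AUC is computed as the Mann-Whitney statistic (rank form, ties count
    one half), which is invariant under strictly monotone transforms of
    the scores.  ROC points are swept over the unique score thresholds
    and returned as an array of (FPR, TPR) rows including (0,0) and (1,1).
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)
    auc = (ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(yt, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(auc)


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31 - 1))


def cross_validate(
    pairs: Sequence[tuple[str, str, int]],
    descriptors: Mapping[str, np.ndarray],
    olpp_config: OLPPConfig | None = None,
    rof_config: RoFConfig | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the descriptor -> OLPP ->
    pair-feature -> Rotation Forest pipeline.

    Per fold: the OLPP model is fitted on the descriptors of proteins that
    occur in training pairs; all proteins are then embedded, pair features
    are concatenated embeddings, the forest is trained on training pairs
    and evaluated on the held-out pairs.  Deterministic given ``seed``.
    """
    olpp_config = olpp_config or OLPPConfig()
    rof_config = rof_config or RoFConfig()
    pairs = list(pairs)
    labels = np.array([p[2] for p in pairs])
    for cls in (0, 1):
        if int(np.sum(labels == cls)) < k_folds:
            raise ValueError(
                f"class {cls} has fewer than k_folds={k_folds} members"
            )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    per_fold: list[dict[str, float]] = []
    fold_scores: list[np.ndarray] = []
    fold_truth: list[np.ndarray] = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(pairs)), labels)):
        train_pairs = [pairs[i] for i in tr_idx]
        test_pairs = [pairs[i] for i in te_idx]
        train_ids = sorted({pid for a, b, _ in train_pairs for pid in (a, b)})
        x_train_desc = np.vstack([np.asarray(descriptors[i], float) for i in train_ids])
        model = olpp_mod.fit_olpp(x_train_desc, olpp_config)
        all_ids = sorted(descriptors)
        emb_mat = olpp_mod.transform(
            model, np.vstack([np.asarray(descriptors[i], float) for i in all_ids])
        )
        embeddings = {pid: emb_mat[i] for i, pid in enumerate(all_ids)}
        feat_train = make_pair_features(embeddings, train_pairs)
        feat_test = make_pair_features(embeddings, test_pairs)
        x_tr = np.vstack([f.values for f in feat_train])
        y_tr = np.array([f.label for f in feat_train])
        x_te = np.vstack([f.values for f in feat_test])
        y_te = np.array([f.label for f in feat_test])
        fold_cfg = RoFConfig(
            n_subsets=rof_config.n_subsets,
            n_trees=rof_config.n_trees,
            sample_fraction=rof_config.sample_fraction,
            bootstrap=rof_config.bootstrap,
            seed=_fold_seed(seed, fold),
        )
        forest = rof_mod.fit(x_tr, y_tr, fold_cfg)
        conf = rof_mod.predict_confidence(forest, x_te)
        scores = conf[:, list(forest.classes).index(1)]
        y_pred = forest.classes[np.argmax(conf, axis=1)]
        m = metrics(confusion(y_te, y_pred))
        _, auc = roc_auc(y_te, scores)
        per_fold.append(
            {"acc": m.acc, "pre": m.pre, "sen": m.sen, "mcc": m.mcc, "auc": auc}
        )
        fold_scores.append(scores)
        fold_truth.append(y_te)
    mean = {k: float(np.mean([f[k] for f in per_fold])) for k in METRIC_NAMES}
    std = {
        k: float(np.std([f[k] for f in per_fold], ddof=1)) if k_folds > 1 else 0.0
        for k in METRIC_NAMES
    }
    report = EvaluationReport(
        per_fold=per_fold,
        mean=mean,
        std=std,
        config={
            "k_folds": k_folds,
            "seed": seed,
            "olpp": asdict(olpp_config),
            "rof": asdict(rof_config),
        },
    )
    # Pooled out-of-fold scores, used by callers that want a single ROC.
    report.config["pooled_scores"] = [
        [int(t), float(s)]
        for t, s in zip(np.concatenate(fold_truth), np.concatenate(fold_scores))
    ]
    return report


def grid_search(
    pairs: Sequence[tuple[str, str, int]],
    descriptors: Mapping[str, np.ndarray],
    k_values: Sequence[int],
    l_values: Sequence[int],
    olpp_config: OLPPConfig | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Full-factorial cross-validated accuracy over the (K, L) grid.

    Returns a DataFrame with columns K, L, mean_acc and a ``best`` flag;
    ties break toward smaller L, then smaller K.
    """
    if not k_values or not l_values:
        raise ValueError("K and L grids must be non-empty")
    rows = []
    for k in k_values:
        for l in l_values:
            report = cross_validate(
                pairs,
                descriptors,
                olpp_config=olpp_config,
                rof_config=RoFConfig(n_subsets=k, n_trees=l),
                k_folds=k_folds,
                seed=seed,
            )
            rows.append({"K": k, "L": l, "mean_acc": report.mean["acc"]})
    df = pd.DataFrame(rows)
    best = df.sort_values(["mean_acc", "L", "K"], ascending=[False, True, True]).index[0]
    df["best"] = False
    df.loc[best, "best"] = True
    return df
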