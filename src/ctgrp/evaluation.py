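"""Confusion-matrix metrics, ROC/AUC, and 10-fold cross-validation.

Convention (important): the POSITIVE class is the NORMAL fetus, so
sensitivity is the detection rate of normal fetuses and specificity the
detection rate of hypoxic (pathological) fetuses — the opposite of the
usual clinical disease-positive convention. ``positive_class`` can be
overridden everywhere.

Metrics: Acc = (TP+TN)/(TP+FP+TN+FN), Se = TP/(TP+FN), Sp = TN/(FP+TN),
reported in percent; display rounding is half-up to two decimals while
full precision is kept internally. AUC is the trapezoidal area under the
empirical ROC curve, equal to the Mann-Whitney concordance probability;
its confidence interval is a seeded stratified bootstrap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .cnn import CNNModel, TrainConfig, build
from .dataset import FoldAssignment
from .records import NORMAL, PATHOLOGICAL, derive_seed

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "confusion",
    "metrics",
    "roc_auc",
    "auc_confidence_interval",
    "cross_validate",
    "display_round",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              positive_class: str = NORMAL) -> ConfusionCounts:
    """Tally TP/FP/FN/TN with the given positive class (default: normal)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted")
    labels = set(t.tolist()) | set(p.tolist())
    if len(labels) > 2:
        raise ValueError(f"labels are not binary: {sorted(labels)}")
    pos_t, pos_p = t == positive_class, p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def metrics(cc: ConfusionCounts) -> Dict[str, float]:
    """Accuracy / sensitivity / specificity in percent (full precision).

    A metric with a zero denominator is returned as ``nan`` (flagged
    undefined rather than raising).
    """
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(cc.tp + cc.tn, cc.total),
        "sensitivity": ratio(cc.tp, cc.tp + cc.fn),
        "specificity": ratio(cc.tn, cc.fp + cc.tn),
    }


def display_round(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for table display (avoids banker's rounding)."""
    if not np.isfinite(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def roc_auc(scores: Sequence[float], true_labels: Sequence[str],
            positive_class: str = NORMAL) -> float:
    """Trapezoidal AUC of positive-class scores; both classes required."""
    y = np.asarray(true_labels) == positive_class
    if y.all() or not y.any():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y.astype(int), np.asarray(scores, dtype=float)))


def auc_confidence_interval(scores, true_labels, positive_class: str = NORMAL,
                            n_boot: int = 2000, alpha: float = 0.05,
                            seed: int = 0) -> Tuple[float, float]:
    """Stratified bootstrap CI for the AUC (resamples within each class)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels) == positive_class
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        i = np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)])
        stats.append(roc_auc_score(y[i].astype(int), scores[i]))
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class CVReport:
    """Per-fold confusion counts and metrics plus their arithmetic means."""
    folds: List[dict]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    mean_auc: float
    n_folds: int
    fold_mode: str
    seed: int
    config: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def cross_validate(images, labels, fold_assignment: FoldAssignment,
                   arch, train_config: TrainConfig = TrainConfig(),
                   val_fraction: float = 0.1, seed: int = 0,
                   n_restarts: int = 1,
                   positive_class: str = NORMAL) -> CVReport:
    """K-fold cross-validation of the CNN on a labeled image dataset.

    For every fold the remaining folds are split 90/10 into training and
    validation (seeded) and a fresh seeded model is trained; when
    ``n_restarts`` > 1, that many independently initialized runs are
    trained and the one with the lowest final training loss is kept — a
    seeded variant of ordinary multi-start fitting, useful when the step
    budget is small. The held-out fold is scored
    by the selected model; reported metrics are the arithmetic means
    across folds. Fully deterministic for a fixed
    (data, folds, config, seed).
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    fold_ids = range(1, fold_assignment.n_folds + 1)
    fold_results = []
    for fold in fold_ids:
        tr = fold_assignment.train_indices(fold)
        te = fold_assignment.test_indices(fold)
        if np.unique(labels[te]).size < 2:
            raise ValueError(f"fold {fold}: held-out set contains a single class")
        fold_seed = derive_seed(seed, f"fold:{fold}")
        rng = np.random.default_rng(fold_seed)
        perm = rng.permutation(tr.size)
        n_val = int(round(val_fraction * tr.size))
        val_idx, tr_idx = tr[perm[:n_val]], tr[perm[n_val:]]

        model = None
        for restart in range(max(n_restarts, 1)):
            run_seed = derive_seed(fold_seed, f"restart:{restart}")
            candidate = build(arch, seed=run_seed)
            cfg_dict = asdict(train_config)
            cfg_dict["seed"] = derive_seed(run_seed, "train")
            candidate.fit(images[tr_idx], labels[tr_idx],
                          images[val_idx] if n_val else None,
                          labels[val_idx] if n_val else None,
                          TrainConfig(**cfg_dict))
            if model is None or (candidate.history[-1]["train_loss"]
                                 < model.history[-1]["train_loss"]):
                model = candidate

        proba, pred = model.predict(images[te])
        cc = confusion(labels[te], pred, positive_class=positive_class)
        m = metrics(cc)
        pos_col = model.classes.index(positive_class)
        auc = roc_auc(proba[:, pos_col], labels[te], positive_class=positive_class)
        fold_results.append(dict(fold=fold, counts=asdict(cc), auc=auc, **m))

    def mean_of(key):
        return float(np.mean([f[key] for f in fold_results]))

    return CVReport(
        folds=fold_results,
        mean_accuracy=mean_of("accuracy"),
        mean_sensitivity=mean_of("sensitivity"),
        mean_specificity=mean_of("specificity"),
        mean_auc=mean_of("auc"),
        n_folds=fold_assignment.n_folds,
        fold_mode=fold_assignment.mode,
        seed=seed,
        config=asdict(train_config),
    )
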