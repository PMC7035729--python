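"""Nested 10-fold cross-validated linear-SVM evaluation.

Outer folds estimate test performance; inner folds, run on each outer
training set only, choose how many of the FDR-ranked features to keep.
Per outer fold:

1. rank features by Fisher discriminant ratio on the outer-training rows;
2. for each candidate count k, measure mean inner-fold validation accuracy
   of a linear SVM on the top-k features (z-scored with inner-training
   statistics);
3. keep the smallest k attaining the maximum mean inner accuracy;
4. refit on the full outer-training set (top-k features, z-scored with
   outer-training statistics) and score the held-out test subset.

Nothing computed from test rows ever reaches ranking, scaling or fitting.
Folds are stratified by class so small datasets cannot produce single-class
test subsets; this is a documented deviation from plain random splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix, rank_by_fdr

__all__ = [
    "ConfusionCounts",
    "CVConfig",
    "FoldResult",
    "CVReport",
    "confusion_metrics",
    "make_nested_folds",
    "evaluate_outer_fold",
    "nested_cv_evaluate",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from confusion counts.

    ACC = (TP+TN)/all, SENS = TP/(TP+FN), SPEC = TN/(TN+FP).  A zero
    denominator means the fold lacked one class entirely and is an error.
    """
    if c.total == 0:
        raise ValueError("degenerate fold: no samples (ACC denominator zero)")
    if c.tp + c.fn == 0:
        raise ValueError("degenerate fold: no positive samples (SENS denominator zero)")
    if c.tn + c.fp == 0:
        raise ValueError("degenerate fold: no negative samples (SPEC denominator zero)")
    acc = (c.tp + c.tn) / c.total
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return acc, sens, spec


@dataclass
class CVConfig:
    n_outer: int = 10
    n_inner: int = 10
    seed: int = 0
    svm_c: float = 1.0
    tune_c: bool = False
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    max_k: int | None = None        # cap on the feature-count scan
    large_descriptor_cap: int = 500  # default cap when n_features exceeds it
    positive_label: str | None = None

    def k_grid(self, n_features: int) -> range:
        cap = self.max_k if self.max_k is not None else (
            n_features if n_features <= self.large_descriptor_cap
            else self.large_descriptor_cap
        )
        return range(1, min(cap, n_features) + 1)


@dataclass
class FoldResult:
    confusion: ConfusionCounts
    k_selected: int
    svm_c: float
    inner_accuracy: float  # mean inner accuracy at the selected (k, C)


@dataclass
class CVReport:
    per_fold: list[FoldResult]
    acc_mean: float
    acc_sd: float
    sens_mean: float
    sens_sd: float
    spec_mean: float
    spec_sd: float
    n_features_mean: float
    n_features_sd: float
    seed: int
    classes: tuple[str, str]
    positive_label: str
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "per_fold": [
                {
                    "tp": f.confusion.tp, "tn": f.confusion.tn,
                    "fp": f.confusion.fp, "fn": f.confusion.fn,
                    "k_selected": f.k_selected, "svm_c": f.svm_c,
                    "inner_accuracy": f.inner_accuracy,
                }
                for f in self.per_fold
            ],
            "acc_mean": self.acc_mean, "acc_sd": self.acc_sd,
            "sens_mean": self.sens_mean, "sens_sd": self.sens_sd,
            "spec_mean": self.spec_mean, "spec_sd": self.spec_sd,
            "n_features_mean": self.n_features_mean,
            "n_features_sd": self.n_features_sd,
            "seed": self.seed,
            "classes": list(self.classes),
            "positive_label": self.positive_label,
            "config": self.config,
        }


def _derived_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def make_nested_folds(labels, n_outer: int = 10, n_inner: int = 10,
                      seed: int = 0):
    """Stratified nested fold plan.

    Returns a list of ``(train_idx, test_idx, inner_splits)`` triples, one
    per outer fold; ``inner_splits`` is a list of ``(fit_idx, val_idx)``
    pairs whose union is exactly the outer training set.  Deterministic for
    a given (labels, n_outer, n_inner, seed).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_outer:
        raise ValueError(
            f"need at least {n_outer} samples per class for {n_outer} outer "
            f"folds; counts: {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed % (2**31))
    plan = []
    for fold_idx, (train_idx, test_idx) in enumerate(outer.split(np.zeros(len(y)), y)):
        inner = StratifiedKFold(
            n_splits=n_inner, shuffle=True,
            random_state=_derived_seed(seed, fold_idx),
        )
        inner_splits = [
            (train_idx[fit], train_idx[val])
            for fit, val in inner.split(np.zeros(len(train_idx)), y[train_idx])
        ]
        plan.append((train_idx, test_idx, inner_splits))
    return plan


def _zscore_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return mu, sd


def _fit_predict(x_tr, y_tr, x_te, c):
    clf = SVC(kernel="linear", C=c)
    clf.fit(x_tr, y_tr)
    return clf.predict(x_te)


def evaluate_outer_fold(values: np.ndarray, y: np.ndarray,
                        train_idx: np.ndarray, test_idx: np.ndarray,
                        inner_splits, cfg: CVConfig):
    """One outer fold: rank, scan k on inner folds, refit, test.

    ``y`` is 0/1 with 1 = positive class.  Returns (FoldResult, ranking
    order used) so callers can inspect what the fold actually selected.
    """
    sub = FeatureMatrix(values=values[train_idx],
                        labels=[str(v) for v in y[train_idx]])
    ranking = rank_by_fdr(sub)
    order = ranking.order

    k_grid = list(cfg.k_grid(values.shape[1]))
    c_grid = list(cfg.c_grid) if cfg.tune_c else [cfg.svm_c]

    # mean inner validation accuracy for each (C, k)
    curve = np.zeros((len(c_grid), len(k_grid)))
    for fit_idx, val_idx in inner_splits:
        mu, sd = _zscore_fit(values[fit_idx])
        x_fit = (values[fit_idx] - mu) / sd
        x_val = (values[val_idx] - mu) / sd
        x_fit = x_fit[:, order]
        x_val = x_val[:, order]
        for ci, c in enumerate(c_grid):
            for ki, k in enumerate(k_grid):
                pred = _fit_predict(x_fit[:, :k], y[fit_idx], x_val[:, :k], c)
                curve[ci, ki] += np.mean(pred == y[val_idx])
    curve /= len(inner_splits)

    best = np.unravel_index(np.argmax(curve), curve.shape)  # first max: smallest k, first C
    # argmax over raveled (C-major) picks first C then smallest k among ties
    # within that C; prefer the smallest k overall among global-max entries:
    max_acc = curve.max()
    ties = np.argwhere(curve == max_acc)
    ki_best = ties[:, 1].min()
    ci_best = ties[ties[:, 1] == ki_best][:, 0].min()
    k_star = k_grid[ki_best]
    c_star = c_grid[ci_best]

    mu, sd = _zscore_fit(values[train_idx])
    x_tr = ((values[train_idx] - mu) / sd)[:, order[:k_star]]
    x_te = ((values[test_idx] - mu) / sd)[:, order[:k_star]]
    pred = _fit_predict(x_tr, y[train_idx], x_te, c_star)
    truth = y[test_idx]
    conf = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )
    result = FoldResult(confusion=conf, k_selected=k_star, svm_c=c_star,
                        inner_accuracy=float(max_acc))
    return result, order


def nested_cv_evaluate(matrix: FeatureMatrix, cfg: CVConfig | None = None) -> CVReport:
    """Full nested cross-validation of a two-class feature matrix."""
    cfg = cfg or CVConfig()
    labs = list(dict.fromkeys(matrix.labels))
    if len(labs) != 2:
        raise ValueError(f"exactly two classes required, found {labs}")
    positive = cfg.positive_label if cfg.positive_label is not None else labs[1]
    if positive not in labs:
        raise ValueError(f"positive label {positive!r} not among classes {labs}")
    y = np.asarray([1 if lab == positive else 0 for lab in matrix.labels])

    plan = make_nested_folds(matrix.labels, cfg.n_outer, cfg.n_inner, cfg.seed)
    per_fold = []
    for train_idx, test_idx, inner_splits in plan:
        result, _ = evaluate_outer_fold(matrix.values, y, train_idx, test_idx,
                                        inner_splits, cfg)
        per_fold.append(result)

    metrics = np.array([confusion_metrics(f.confusion) for f in per_fold])
    ks = np.array([f.k_selected for f in per_fold], dtype=float)

    def mean_sd(v: np.ndarray) -> tuple[float, float]:
        return float(v.mean()), float(v.std(ddof=1))

    acc_mean, acc_sd = mean_sd(metrics[:, 0])
    sens_mean, sens_sd = mean_sd(metrics[:, 1])
    spec_mean, spec_sd = mean_sd(metrics[:, 2])
    k_mean, k_sd = mean_sd(ks)
    negative = labs[0] if positive == labs[1] else labs[1]
    return CVReport(
        per_fold=per_fold,
        acc_mean=acc_mean, acc_sd=acc_sd,
        sens_mean=sens_mean, sens_sd=sens_sd,
        spec_mean=spec_mean, spec_sd=spec_sd,
        n_features_mean=k_mean, n_features_sd=k_sd,
        seed=cfg.seed,
        classes=(negative, positive),
        positive_label=positive,
        config=asdict(cfg),
    )
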