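"""Stratified cross-validation, confusion-matrix metrics and the grouped-control design.

Sensitivity = TP/CP, specificity = TN/CN and accuracy = (TP+TN)/(CP+CN),
where CP/CN are the numbers of true positive/negative patients in a fold.
Fold metrics are macro-averaged (mean of per-fold values) and their spread
is reported as the population standard deviation (divide by N, not N-1),
which serves as the stability measure of the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import factorization
from .assessment import predict_risk, train_classifier
from .cohort import CASE

__all__ = [
    "FoldMetrics",
    "EvaluationResult",
    "GroupedEvaluation",
    "stratified_kfold",
    "compute_metrics",
    "pooled_metrics",
    "aggregate",
    "cross_validate",
    "grouped_control_evaluation",
    "UndefinedMetricWarning",
]


class UndefinedMetricWarning(UserWarning):
    """A metric's denominator was zero; its value is NaN, not silently 0."""


@dataclass(frozen=True)
class FoldMetrics:
    """Confusion counts and derived proportions for one evaluation fold."""

    true_positive: int
    true_negative: int
    condition_positive: int
    condition_negative: int
    sensitivity: float
    specificity: float
    accuracy: float

    def __post_init__(self) -> None:
        if self.true_positive > self.condition_positive:
            raise ValueError("TP cannot exceed CP")
        if self.true_negative > self.condition_negative:
            raise ValueError("TN cannot exceed CN")


@dataclass
class EvaluationResult:
    """Per-fold metrics with their macro means and population SDs."""

    per_fold: list[FoldMetrics]
    mean_sensitivity: float
    sd_sensitivity: float
    mean_specificity: float
    sd_specificity: float
    mean_accuracy: float
    sd_accuracy: float
    n_folds: int
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": [
                    self.mean_sensitivity,
                    self.mean_specificity,
                    self.mean_accuracy,
                ],
                "sd": [
                    self.sd_sensitivity,
                    self.sd_specificity,
                    self.sd_accuracy,
                ],
            },
            index=["sensitivity", "specificity", "accuracy"],
        )

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.per_fold])

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = yaml.safe_dump(
            {
                "n_folds": self.n_folds,
                "seed": self.seed,
                "mean_sensitivity": float(self.mean_sensitivity),
                "sd_sensitivity": float(self.sd_sensitivity),
                "mean_specificity": float(self.mean_specificity),
                "sd_specificity": float(self.sd_specificity),
                "mean_accuracy": float(self.mean_accuracy),
                "sd_accuracy": float(self.sd_accuracy),
            },
            sort_keys=False,
        )
        if path is not None:
            Path(path).write_text(doc, encoding="utf-8")
        return doc


def stratified_kfold(
    labels: Sequence[str], k: int, seed: int
) -> np.ndarray:
    """Assign each patient to one of ``k`` folds, stratified by class.

    Within each class the indices are shuffled by a seeded generator and
    dealt round-robin from a random starting fold, so per-class counts
    across folds differ by at most one and the assignment is reproducible.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} patients")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 1:  # pragma: no cover - np.unique cannot yield 0
        raise ValueError("each class needs at least one member")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        start = int(rng.integers(k))
        folds[idx] = (np.arange(idx.size) + start) % k
    return folds


def compute_metrics(
    truth: Sequence[str],
    predicted: Sequence[str],
    *,
    positive: str = CASE,
) -> FoldMetrics:
    """Confusion counts and sensitivity/specificity/accuracy for one fold."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    pos_t = truth == positive
    pos_p = predicted == positive
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    cp = int(np.sum(pos_t))
    cn = int(truth.size - cp)

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(
                f"{name} undefined: zero denominator", UndefinedMetricWarning,
                stacklevel=3,
            )
            return float("nan")
        return num / den

    return FoldMetrics(
        true_positive=tp,
        true_negative=tn,
        condition_positive=cp,
        condition_negative=cn,
        sensitivity=ratio(tp, cp, "sensitivity"),
        specificity=ratio(tn, cn, "specificity"),
        accuracy=ratio(tp + tn, cp + cn, "accuracy"),
    )


def pooled_metrics(per_fold: Sequence[FoldMetrics]) -> FoldMetrics:
    """Metrics on the confusion counts summed over folds (micro average)."""
    tp = sum(f.true_positive for f in per_fold)
    tn = sum(f.true_negative for f in per_fold)
    cp = sum(f.condition_positive for f in per_fold)
    cn = sum(f.condition_negative for f in per_fold)
    return FoldMetrics(
        tp, tn, cp, cn,
        sensitivity=tp / cp if cp else float("nan"),
        specificity=tn / cn if cn else float("nan"),
        accuracy=(tp + tn) / (cp + cn) if cp + cn else float("nan"),
    )


def aggregate(
    per_fold: Sequence[FoldMetrics], *, seed: int | None = None
) -> EvaluationResult:
    """Macro-average fold metrics; spread is the population SD (divide by N)."""
    if not per_fold:
        raise ValueError("no folds to aggregate")
    sens = np.array([f.sensitivity for f in per_fold])
    spec = np.array([f.specificity for f in per_fold])
    acc = np.array([f.accuracy for f in per_fold])
    return EvaluationResult(
        per_fold=list(per_fold),
        mean_sensitivity=float(sens.mean()),
        sd_sensitivity=float(sens.std()),
        mean_specificity=float(spec.mean()),
        sd_specificity=float(spec.std()),
        mean_accuracy=float(acc.mean()),
        sd_accuracy=float(acc.std()),
        n_folds=len(per_fold),
        seed=seed,
    )


def _fold_seed(seed: int, offset: int) -> int:
    return int((seed + 7919 * (offset + 1)) % (2**31))


def cross_validate(
    PD,
    labels: Sequence[str],
    rank: int,
    *,
    n_folds: int = 10,
    seed: int = 0,
    C: float = 2.0,
    gamma: float = 0.03125,
    mode: str = "inductive",
    max_iter: int = 300,
    tol: float = 1e-4,
    positive: str = CASE,
    pooled: bool = False,
) -> EvaluationResult:
    """Stratified k-fold cross-validation of the factorization + classifier stack.

    ``mode="inductive"`` (the default) refits the factorization on each
    training split and folds test rows into the learned space, so test
    patients never leak into the factors. ``mode="transductive"`` factorizes
    the full matrix once before splitting, reproducing the published
    protocol at the cost of feature-level leakage.

    ``pooled=True`` additionally replaces the macro averages with metrics on
    the summed confusion counts.
    """
    labels = np.asarray(labels)
    if mode not in ("inductive", "transductive"):
        raise ValueError(f"unknown mode {mode!r}")
    folds = stratified_kfold(labels, n_folds, seed)
    per_fold: list[FoldMetrics] = []

    if mode == "transductive":
        fm = factorization.nmf_fit(
            PD, rank, seed=_fold_seed(seed, -1), max_iter=max_iter, tol=tol
        )
        features = fm.PR
        for f in range(n_folds):
            train, test = folds != f, folds == f
            model = train_classifier(
                features[train], labels[train], C=C, gamma=gamma
            )
            pred, _ = predict_risk(model, features[test])
            per_fold.append(
                compute_metrics(labels[test], pred, positive=positive)
            )
    else:
        for f in range(n_folds):
            train_idx = np.flatnonzero(folds != f)
            test_idx = np.flatnonzero(folds == f)
            fm = factorization.nmf_fit(
                PD[train_idx],
                rank,
                seed=_fold_seed(seed, f),
                max_iter=max_iter,
                tol=tol,
            )
            model = train_classifier(
                fm.PR, labels[train_idx], C=C, gamma=gamma
            )
            test_features = np.vstack(
                [factorization.fold_in(PD[i], fm.DR) for i in test_idx]
            )
            pred, _ = predict_risk(model, test_features)
            per_fold.append(
                compute_metrics(labels[test_idx], pred, positive=positive)
            )

    result = aggregate(per_fold, seed=seed)
    if pooled:
        p = pooled_metrics(per_fold)
        result.mean_sensitivity = p.sensitivity
        result.mean_specificity = p.specificity
        result.mean_accuracy = p.accuracy
    return result


@dataclass
class GroupedEvaluation:
    """Results over disjoint control groups sharing one case set."""

    results: list[EvaluationResult]
    grand: pd.DataFrame  # mean/sd over groups of the per-group means


def grouped_control_evaluation(
    PD_cases,
    PD_controls,
    *,
    rank: int,
    n_groups: int = 50,
    group_size: int = 500,
    n_folds: int = 10,
    seed: int = 0,
    positive: str = CASE,
    control_label: str = "control",
    **cv_kwargs,
) -> GroupedEvaluation:
    """Evaluate one case set against many disjoint control groups.

    The controls are partitioned (after a seeded shuffle) into ``n_groups``
    disjoint groups of ``group_size``; each group is combined with the same
    cases and the evaluation protocol is run on the union. The defaults
    mirror a 50-group x 500-control design.
    """
    n_controls = PD_controls.shape[0]
    if n_groups * group_size > n_controls:
        raise ValueError(
            f"need {n_groups * group_size} controls, have {n_controls}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_controls)
    case_labels = np.full(PD_cases.shape[0], positive)
    results = []
    for g in range(n_groups):
        grp = order[g * group_size : (g + 1) * group_size]
        block = (
            sp.vstack([sp.csr_matrix(PD_cases), sp.csr_matrix(PD_controls[grp])])
            if sp.issparse(PD_cases) or sp.issparse(PD_controls)
            else np.vstack([PD_cases, PD_controls[grp]])
        )
        labels = np.concatenate(
            [case_labels, np.full(grp.size, control_label)]
        )
        results.append(
            cross_validate(
                block,
                labels,
                rank,
                n_folds=n_folds,
                seed=_fold_seed(seed, g),
                positive=positive,
                **cv_kwargs,
            )
        )
    grand = pd.DataFrame(
        {
            "mean": {
                "sensitivity": np.mean([r.mean_sensitivity for r in results]),
                "specificity": np.mean([r.mean_specificity for r in results]),
                "accuracy": np.mean([r.mean_accuracy for r in results]),
            },
            "sd": {
                "sensitivity": np.std([r.mean_sensitivity for r in results]),
                "specificity": np.std([r.mean_specificity for r in results]),
                "accuracy": np.std([r.mean_accuracy for r in results]),
            },
        }
    )
    return GroupedEvaluation(results=results, grand=grand)
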