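"""Risk classification on latent-factor loadings and parameter selection.

A soft-margin SVM with an RBF kernel is trained on the rows of PR (each
patient's loading on the R latent risk factors). Defaults C = 2 and
gamma = 0.03125 (= 2^-5); the grid-search helper sweeps the usual
powers-of-two grids when these need re-deriving on new data. The rank sweep
evaluates a list of candidate R values by stratified cross-validation and
``select_rank`` applies the selection rule: among ranks whose
sensitivity-specificity gap is acceptable, prefer the highest mean accuracy,
then the lowest accuracy SD, then the smallest rank.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .cohort import CASE

__all__ = [
    "RiskModel",
    "SweepRow",
    "DEFAULT_C",
    "DEFAULT_GAMMA",
    "train_classifier",
    "predict_risk",
    "grid_search",
    "sweep_rank",
    "select_rank",
]

DEFAULT_C = 2.0
DEFAULT_GAMMA = 0.03125  # 2**-5


@dataclass
class RiskModel:
    """A fitted RBF-kernel risk classifier over factor loadings."""

    classifier: SVC
    C: float
    gamma: float
    positive: str
    negative: str
    n_features: int
    factor_model: object | None = None  # FactorModel the features came from

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass(frozen=True)
class SweepRow:
    """One row of a rank sweep: CV performance at a candidate factor count."""

    R: int
    mean_sensitivity: float
    mean_specificity: float
    mean_accuracy: float
    sd_accuracy: float
    gap: float
    valid: bool = True


def train_classifier(
    features,
    labels: Sequence[str],
    *,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    positive: str = CASE,
    factor_model=None,
) -> RiskModel:
    """Fit the RBF-SVM risk classifier on one loading vector per patient."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("one label per feature row required")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(
            f"need exactly two classes to train, got {classes.tolist()}"
        )
    if positive not in classes:
        raise ValueError(f"positive label {positive!r} absent from labels")
    negative = classes[classes != positive][0]
    y = (labels == positive).astype(int)
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(features, y)
    return RiskModel(
        classifier=clf,
        C=C,
        gamma=gamma,
        positive=str(positive),
        negative=str(negative),
        n_features=features.shape[1],
        factor_model=factor_model,
    )


def predict_risk(model: RiskModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Predict a {case, control} label and a real decision score per row.

    Scores are the signed distances to the separating surface; positive
    scores point toward the positive (case) class, so they can be
    re-thresholded downstream.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be 2-D")
    if features.shape[0] == 0:
        return np.empty(0, dtype=object), np.empty(0)
    if features.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {features.shape[1]} does not match the "
            f"trained dimension {model.n_features}"
        )
    scores = model.classifier.decision_function(features)
    labels = np.where(scores > 0, model.positive, model.negative)
    return labels, scores


def _default_C_grid() -> np.ndarray:
    return 2.0 ** np.arange(-5, 16, 2, dtype=float)


def _default_gamma_grid() -> np.ndarray:
    return 2.0 ** np.arange(-15, 4, 2, dtype=float)


def grid_search(
    features,
    labels: Sequence[str],
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    *,
    n_folds: int = 5,
    seed: int = 0,
    positive: str = CASE,
) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive (C, gamma) search by inner cross-validated accuracy.

    Ties go to the smaller C, then the smaller gamma. Default grids are the
    customary powers of two: C in 2^-5..2^15, gamma in 2^-15..2^3.
    """
    from .evaluation import stratified_kfold  # local import breaks the cycle

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    C_values = sorted(float(c) for c in (C_grid if C_grid is not None else _default_C_grid()))
    g_values = sorted(float(g) for g in (gamma_grid if gamma_grid is not None else _default_gamma_grid()))
    if not C_values or not g_values:
        raise ValueError("grids must be non-empty")
    folds = stratified_kfold(labels, n_folds, seed)
    rows = []
    best: tuple[float, float] | None = None
    best_acc = -math.inf
    for C in C_values:
        for gamma in g_values:
            accs = []
            for f in range(n_folds):
                train, test = folds != f, folds == f
                model = train_classifier(
                    features[train], labels[train], C=C, gamma=gamma,
                    positive=positive,
                )
                pred, _ = predict_risk(model, features[test])
                accs.append(float(np.mean(pred == labels[test])))
            mean_acc = float(np.mean(accs))
            rows.append({"C": C, "gamma": gamma, "cv_accuracy": mean_acc})
            if mean_acc > best_acc:  # strict: earlier (smaller) pairs win ties
                best_acc = mean_acc
                best = (C, gamma)
    assert best is not None
    return best[0], best[1], pd.DataFrame(rows)


def sweep_rank(
    PD,
    labels: Sequence[str],
    R_values: Sequence[int],
    *,
    n_folds: int = 10,
    seed: int = 0,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    mode: str = "inductive",
    max_iter: int = 300,
    tol: float = 1e-4,
) -> list[SweepRow]:
    """Cross-validate the pipeline at each candidate rank.

    The published protocol swept R from 100 to 900 in steps of 100 on a
    balanced 500/500 sample; any list of candidate ranks below the number of
    codes M is accepted. A rank >= M is flagged invalid rather than fitted.
    """
    from .evaluation import cross_validate

    m = PD.shape[1]
    rows: list[SweepRow] = []
    for R in R_values:
        if not (0 < R < m):
            warnings.warn(
                f"rank {R} is not in (0, M={m}); row flagged invalid",
                stacklevel=2,
            )
            rows.append(
                SweepRow(R, float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"), valid=False)
            )
            continue
        res = cross_validate(
            PD, labels, R, n_folds=n_folds, seed=seed, C=C, gamma=gamma,
            mode=mode, max_iter=max_iter, tol=tol,
        )
        rows.append(
            SweepRow(
                R=R,
                mean_sensitivity=res.mean_sensitivity,
                mean_specificity=res.mean_specificity,
                mean_accuracy=res.mean_accuracy,
                sd_accuracy=res.sd_accuracy,
                gap=abs(res.mean_sensitivity - res.mean_specificity),
            )
        )
    return rows


def sweep_frame(rows: Sequence[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def select_rank(rows: Sequence[SweepRow], max_gap: float = 0.05) -> int:
    """Apply the rank-selection rule to a sweep table.

    Among valid rows whose sensitivity-specificity gap is strictly below
    ``max_gap`` (default 5%), pick the highest mean accuracy; break ties by
    the lowest accuracy SD, then the smallest rank. If no row satisfies the
    gap constraint, fall back to the minimal-gap row with a warning. Pure in
    its inputs: row order never matters.
    """
    valid = [r for r in rows if r.valid]
    if not valid:
        raise ValueError("no valid sweep rows")
    eligible = [r for r in valid if r.gap < max_gap]
    if not eligible:
        warnings.warn(
            f"no rank has a sensitivity-specificity gap below {max_gap}; "
            "falling back to the minimal-gap rank",
            stacklevel=2,
        )
        return min(valid, key=lambda r: (r.gap, r.R)).R
    return min(
        eligible, key=lambda r: (-r.mean_accuracy, r.sd_accuracy, r.R)
    ).R
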