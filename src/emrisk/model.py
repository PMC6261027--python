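"""High-level modelling interface: build, fit, inspect, predict.

``DiseaseRiskModel`` bundles the whole stack — binary patient-disease
matrix, non-negative factorization at a chosen rank, and the RBF-SVM risk
classifier — behind a fit/results pair:

>>> model = DiseaseRiskModel(pdm, rank=5)
>>> results = model.fit(seed=7)
>>> print(results.summary())
>>> labels, scores = results.predict(new_histories)

``fit`` factorizes the matrix, trains the classifier on the loadings, and
(by default) estimates out-of-sample performance by stratified k-fold
cross-validation in inductive mode: each training split is refactorized and
test patients are folded into that split's factor space.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import assessment, evaluation, factorization
from .cohort import CASE, Cohort, PatientHistory, build_cohort
from .matrix import PatientDiseaseMatrix, build_matrix, build_vocabulary
from .records import DEFAULT_WINDOW, filter_noise, read_diagnostic_records

__all__ = ["DiseaseRiskModel", "DiseaseRiskResults"]


class DiseaseRiskModel:
    """Early disease risk assessment model over a binary diagnosis matrix.

    Parameters
    ----------
    pdm
        The patient-disease matrix with per-row case/control labels.
    rank
        Number of latent risk factors R (must be below the code count M).
    C, gamma
        RBF-SVM parameters; defaults C=2, gamma=2**-5.
    mode
        ``"inductive"`` (default) or ``"transductive"`` cross-validation
        protocol; see :func:`emrisk.evaluation.cross_validate`.
    """

    def __init__(
        self,
        pdm: PatientDiseaseMatrix,
        *,
        rank: int = 200,
        C: float = assessment.DEFAULT_C,
        gamma: float = assessment.DEFAULT_GAMMA,
        mode: str = "inductive",
    ):
        m = pdm.shape[1]
        if not (0 < rank < m):
            raise ValueError(f"rank must satisfy 0 < R < M={m}, got {rank}")
        self.pdm = pdm
        self.rank = rank
        self.C = C
        self.gamma = gamma
        self.mode = mode

    # ------------------------------------------------------------------
    # constructors
    @classmethod
    def from_histories(
        cls,
        histories: Sequence[PatientHistory],
        *,
        exclude_codes: Sequence[str] = (),
        **kwargs,
    ) -> "DiseaseRiskModel":
        vocab = build_vocabulary(histories, exclude=exclude_codes)
        return cls(build_matrix(histories, vocab), **kwargs)

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "DiseaseRiskModel":
        return cls.from_histories(
            cohort.histories, exclude_codes=[cohort.target_code], **kwargs
        )

    @classmethod
    def from_files(
        cls,
        records_path: str | Path,
        registry_path: str | Path,
        *,
        target_code: str = "71400",
        min_dx: int = 2,
        window: tuple[dt.date, dt.date] = DEFAULT_WINDOW,
        id_length: int | None = 10,
        **kwargs,
    ) -> "DiseaseRiskModel":
        """Run the full preprocessing chain from raw files to a model."""
        records = read_diagnostic_records(records_path)
        clean, _ = filter_noise(records, window=window, id_length=id_length)
        registry = set(
            Path(registry_path).read_text(encoding="utf-8").split()
        )
        cohort = build_cohort(
            clean, registry, target_code, min_dx=min_dx, window=window
        )
        return cls.from_cohort(cohort, **kwargs)

    # ------------------------------------------------------------------
    def fit(
        self,
        *,
        seed: int = 0,
        max_iter: int = 500,
        tol: float = 1e-4,
        n_restarts: int = 1,
        cv_folds: int | None = 10,
    ) -> "DiseaseRiskResults":
        """Factorize, train the classifier, and cross-validate.

        ``cv_folds=None`` skips cross-validation (the results then carry
        only the fitted factors and classifier).
        """
        fm = factorization.nmf_fit(
            self.pdm.PD,
            self.rank,
            seed=seed,
            max_iter=max_iter,
            tol=tol,
            n_restarts=n_restarts,
            vocab=self.pdm.col_codes,
        )
        risk = assessment.train_classifier(
            fm.PR,
            self.pdm.labels_array,
            C=self.C,
            gamma=self.gamma,
            factor_model=fm,
        )
        cv = None
        if cv_folds is not None:
            cv = evaluation.cross_validate(
                self.pdm.PD,
                self.pdm.labels_array,
                self.rank,
                n_folds=cv_folds,
                seed=seed,
                C=self.C,
                gamma=self.gamma,
                mode=self.mode,
                max_iter=max_iter,
                tol=tol,
            )
        return DiseaseRiskResults(self, fm, risk, cv, seed=seed)

    def sweep_rank(
        self,
        R_values: Sequence[int],
        *,
        n_folds: int = 10,
        seed: int = 0,
        max_gap: float = 0.05,
        **kwargs,
    ) -> tuple[pd.DataFrame, int]:
        """Cross-validate candidate ranks and apply the selection rule."""
        rows = assessment.sweep_rank(
            self.pdm.PD,
            self.pdm.labels_array,
            R_values,
            n_folds=n_folds,
            seed=seed,
            C=self.C,
            gamma=self.gamma,
            mode=self.mode,
            **kwargs,
        )
        return assessment.sweep_frame(rows), assessment.select_rank(
            rows, max_gap=max_gap
        )


@dataclass
class DiseaseRiskResults:
    """Fitted factors, classifier and cross-validated performance."""

    model: DiseaseRiskModel
    factor_model: factorization.FactorModel
    risk_model: assessment.RiskModel
    evaluation: evaluation.EvaluationResult | None
    seed: int

    @property
    def loadings(self) -> np.ndarray:
        """Patient loadings on the latent risk factors (rows of PR)."""
        return self.factor_model.PR

    @property
    def factors(self) -> pd.DataFrame:
        """Disease loadings DR as codes x factors."""
        return pd.DataFrame(
            self.factor_model.DR,
            index=self.model.pdm.col_codes,
            columns=[f"factor_{r}" for r in range(self.factor_model.R)],
        )

    def top_codes(self, factor: int, n: int = 10) -> pd.Series:
        """The ``n`` diagnosis codes loading highest on one latent factor."""
        return self.factors.iloc[:, factor].sort_values(ascending=False)[:n]

    def predict(
        self, histories_or_rows
    ) -> tuple[np.ndarray, np.ndarray]:
        """Fold unseen patients into the factor space and score their risk.

        Accepts either a sequence of :class:`PatientHistory` (mapped onto the
        training vocabulary) or an already-built binary matrix with matching
        columns. Returns predicted labels and decision scores.
        """
        rows = histories_or_rows
        if (
            isinstance(rows, (list, tuple))
            and rows
            and isinstance(rows[0], PatientHistory)
        ):
            rows = build_matrix(rows, self.model.pdm.col_codes).PD
        rows = np.atleast_2d(
            np.asarray(rows.todense() if hasattr(rows, "todense") else rows,
                       dtype=float)
        )
        feats = np.vstack(
            [factorization.fold_in(r, self.factor_model.DR) for r in rows]
        ) if rows.shape[0] else np.empty((0, self.factor_model.R))
        return assessment.predict_risk(self.risk_model, feats)

    def summary(self) -> str:
        """A text table of the fit: dimensions, parameters, CV performance."""
        pdm = self.model.pdm
        n_cases = int(np.sum(pdm.labels_array == CASE))
        lines = [
            "Early Disease Risk Assessment",
            "=" * 46,
            f"patients              {pdm.shape[0]:>10d}"
            f"   (cases {n_cases}, controls {pdm.shape[0] - n_cases})",
            f"diagnosis codes (M)   {pdm.shape[1]:>10d}",
            f"latent factors (R)    {self.model.rank:>10d}",
            f"NMF iterations        {self.factor_model.n_iter:>10d}"
            f"   final objective {self.factor_model.final_objective:.4f}",
            f"SVM (RBF)             C={self.model.C:g}, "
            f"gamma={self.model.gamma:g}",
            f"seed                  {self.seed:>10d}",
        ]
        if self.evaluation is not None:
            ev = self.evaluation
            lines += [
                "-" * 46,
                f"{ev.n_folds}-fold stratified CV ({self.model.mode}):",
                f"  sensitivity   {ev.mean_sensitivity:7.4f} "
                f"(SD {ev.sd_sensitivity:.4f})",
                f"  specificity   {ev.mean_specificity:7.4f} "
                f"(SD {ev.sd_specificity:.4f})",
                f"  accuracy      {ev.mean_accuracy:7.4f} "
                f"(SD {ev.sd_accuracy:.4f})",
            ]
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Plot the NMF objective trace (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.factor_model.objective_trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel(r"$\|PD - PR\,DR^T\|_F^2$")
        ax.set_title(f"NMF objective (R={self.factor_model.R})")
        return ax
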