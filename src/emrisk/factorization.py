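"""Latent risk-factor discovery by non-negative matrix factorization.

The binary patient-disease matrix PD (N x M) is approximated by the product
of two nonnegative factor matrices,

    PD  ~=  PR . DR^T,      PR: N x R,  DR: M x R,  R < M,

minimizing the squared Frobenius reconstruction error

    f(PR, DR) = || PD - PR . DR^T ||_F^2

by the classic alternating multiplicative updates

    PR <- PR * (PD . DR)   / (PR . (DR^T DR) + eps)
    DR <- DR * (PD^T . PR) / (DR . (PR^T PR) + eps)

(elementwise product and division). These updates keep the factors
nonnegative and never increase the objective, so the recorded objective
trace is non-increasing up to floating-point slack. Each row of PR is a
patient's loading on the R latent risk factors and serves as the feature
vector of the downstream risk classifier; each column of DR describes one
latent factor as a weighting over diagnosis codes.

Unseen patients are *folded in*: with DR held fixed, a single binary history
row is projected into the factor space by the same multiplicative update on
its loading vector. This keeps evaluation inductive — test patients never
influence the learned factor space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

__all__ = [
    "FactorModel",
    "nmf_objective",
    "nmf_fit",
    "fold_in",
    "save_factor_model",
    "load_factor_model",
    "NumericalError",
]

#: Denominator stabilizer for the multiplicative updates.
EPS = 1e-12


class NumericalError(FloatingPointError):
    """Non-finite values appeared during the factorization iterations."""

    def __init__(self, message: str, iteration: int):
        super().__init__(message)
        self.iteration = iteration


@dataclass
class FactorModel:
    """A fitted nonnegative factorization PD ~= PR . DR^T."""

    PR: np.ndarray
    DR: np.ndarray
    R: int
    objective_trace: np.ndarray
    seed: int
    n_iter: int
    vocab: list[str] | None = None

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def reconstruction(self) -> np.ndarray:
        return self.PR @ self.DR.T

    def row_residuals(self, PD) -> np.ndarray:
        """Per-row squared reconstruction error against ``PD``."""
        dense = _as_dense(PD)
        return ((dense - self.reconstruction()) ** 2).sum(axis=1)


def _as_dense(PD) -> np.ndarray:
    if sp.issparse(PD):
        return np.asarray(PD.todense(), dtype=float)
    return np.asarray(PD, dtype=float)


def nmf_objective(PD, PR: np.ndarray, DR: np.ndarray) -> float:
    """Squared Frobenius norm of the residual, ``||PD - PR.DR^T||_F^2``.

    Accepts a dense or sparse ``PD``; for sparse input the norm is expanded
    as ``||PD||^2 - 2<PD, PR.DR^T> + tr((PR^T PR)(DR^T DR))`` so the dense
    N x M residual is never materialized.
    """
    PR = np.asarray(PR, dtype=float)
    DR = np.asarray(DR, dtype=float)
    n, m = (PD.shape[0], PD.shape[1])
    if PR.shape[0] != n or DR.shape[0] != m or PR.shape[1] != DR.shape[1]:
        raise ValueError(
            f"non-conformable shapes: PD {PD.shape}, PR {PR.shape}, DR {DR.shape}"
        )
    if sp.issparse(PD):
        pd_sq = float((PD.data.astype(float) ** 2).sum())
        cross = float(np.sum((PD.T @ PR) * DR))
        recon_sq = float(np.sum((PR.T @ PR) * (DR.T @ DR)))
        return pd_sq - 2.0 * cross + recon_sq
    PD = np.asarray(PD, dtype=float)
    return float(((PD - PR @ DR.T) ** 2).sum())


def nmf_fit(
    PD,
    rank: int,
    *,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_restarts: int = 1,
    vocab: Sequence[str] | None = None,
) -> FactorModel:
    """Fit the factorization by alternating multiplicative updates.

    Parameters
    ----------
    PD
        Nonnegative N x M matrix (dense array or scipy sparse).
    rank
        Number of latent risk factors R; must satisfy 0 < R < M.
    seed
        Seed for the Uniform(0, 1) factor initialization. Restart ``i``
        uses ``seed + i``.
    max_iter, tol
        Iterate until the relative objective change drops below ``tol`` or
        ``max_iter`` full update sweeps have run. The objective is recorded
        after every sweep, with the initial value at index 0.
    n_restarts
        Number of seeded restarts; the fit with the lowest final objective
        is returned.
    """
    n, m = PD.shape
    if not (0 < rank < m):
        raise ValueError(f"rank must satisfy 0 < R < M={m}, got {rank}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if sp.issparse(PD):
        if PD.nnz and PD.data.min() < 0:
            raise ValueError("PD must be nonnegative")
        PD = PD.astype(float).tocsr()
        PDT = PD.T.tocsr()
    else:
        PD = np.asarray(PD, dtype=float)
        if PD.size and PD.min() < 0:
            raise ValueError("PD must be nonnegative")
        PDT = PD.T

    best: FactorModel | None = None
    for restart in range(n_restarts):
        run_seed = seed + restart
        rng = np.random.default_rng(run_seed)
        PR = rng.random((n, rank))
        DR = rng.random((m, rank))
        trace = [nmf_objective(PD, PR, DR)]
        n_iter = 0
        for it in range(1, max_iter + 1):
            PR *= (PD @ DR) / (PR @ (DR.T @ DR) + EPS)
            DR *= (PDT @ PR) / (DR @ (PR.T @ PR) + EPS)
            obj = nmf_objective(PD, PR, DR)
            if not np.isfinite(obj):
                raise NumericalError(
                    f"non-finite objective at iteration {it}", iteration=it
                )
            trace.append(obj)
            n_iter = it
            prev = trace[-2]
            if abs(prev - obj) < tol * max(prev, EPS):  # tol=0 never stops
                break
        # fix the scale indeterminacy of PR.DR^T: unit-norm DR columns put
        # all factor scale into PR, keeping classifier features comparable
        # across fits (the reconstruction and objective are unchanged)
        norms = np.linalg.norm(DR, axis=0)
        norms[norms == 0] = 1.0
        DR /= norms
        PR *= norms
        model = FactorModel(
            PR=PR,
            DR=DR,
            R=rank,
            objective_trace=np.asarray(trace),
            seed=run_seed,
            n_iter=n_iter,
            vocab=list(vocab) if vocab is not None else None,
        )
        if best is None or model.final_objective < best.final_objective:
            best = model
    assert best is not None
    return best


def fold_in(
    row,
    DR: np.ndarray,
    *,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> np.ndarray:
    """Project one binary history row into a fitted factor space.

    Solves ``min_h ||row - h . DR^T||^2`` over nonnegative ``h`` with DR held
    fixed, by the multiplicative update ``h <- h * (row.DR) / (h.(DR^T DR) + eps)``
    from an all-ones start. An all-zero row maps to the all-zero loading
    (zero numerator fixed point). This single-row problem is convex, so the
    update converges to the nonnegative least-squares projection.
    """
    if sp.issparse(row):
        row = np.asarray(row.todense()).ravel()
    row = np.asarray(row, dtype=float).ravel()
    DR = np.asarray(DR, dtype=float)
    m, r = DR.shape
    if row.shape[0] != m:
        raise ValueError(
            f"row has {row.shape[0]} codes but the factor space expects {m}"
        )
    if not row.any():
        return np.zeros(r)
    gram = DR.T @ DR
    numer = row @ DR
    h = np.ones(r)
    for _ in range(max_iter):
        h_new = h * numer / (h @ gram + EPS)
        delta = float(np.max(np.abs(h_new - h)))
        h = h_new
        if delta < tol * max(float(np.max(h)), 1.0):
            break
    return h


def save_factor_model(model: FactorModel, out_dir: str | Path) -> None:
    """Persist a fitted model as text: PR/DR as MatrixMarket, trace as CSV, metadata as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "PR.mtx"), sp.coo_matrix(model.PR))
    mmwrite(str(out / "DR.mtx"), sp.coo_matrix(model.DR))
    np.savetxt(
        out / "trace.csv",
        np.column_stack(
            [np.arange(len(model.objective_trace)), model.objective_trace]
        ),
        delimiter=",",
        header="iteration,objective",
        comments="",
    )
    meta = {"R": model.R, "seed": model.seed, "n_iter": model.n_iter}
    (out / "meta.yaml").write_text(yaml.safe_dump(meta), encoding="utf-8")
    if model.vocab is not None:
        (out / "vocab.txt").write_text(
            "\n".join(model.vocab) + "\n", encoding="utf-8"
        )


def load_factor_model(in_dir: str | Path) -> FactorModel:
    """Load a model written by :func:`save_factor_model`."""
    src = Path(in_dir)
    PR = np.asarray(sp.coo_matrix(mmread(str(src / "PR.mtx"))).todense())
    DR = np.asarray(sp.coo_matrix(mmread(str(src / "DR.mtx"))).todense())
    trace = np.loadtxt(src / "trace.csv", delimiter=",", skiprows=1, ndmin=2)
    meta = yaml.safe_load((src / "meta.yaml").read_text(encoding="utf-8"))
    vocab_path = src / "vocab.txt"
    vocab = (
        vocab_path.read_text(encoding="utf-8").splitlines()
        if vocab_path.exists()
        else None
    )
    if PR.shape[1] != meta["R"] or DR.shape[1] != meta["R"]:
        raise ValueError("factor shapes disagree with stored rank")
    return FactorModel(
        PR=PR,
        DR=DR,
        R=meta["R"],
        objective_trace=trace[:, 1],
        seed=meta["seed"],
        n_iter=meta["n_iter"],
        vocab=vocab,
    )
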