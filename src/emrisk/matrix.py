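"""The binary patient-disease diagnosis matrix and its on-disk form.

Entry (n, m) is 1 iff patient n was diagnosed at least once with code m in
their (censored) history — presence, not counts. The matrix is stored sparse
(CSR) and persisted as a MatrixMarket coordinate file with plain-text
sidecars for row identifiers, column codes and row labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .cohort import PatientHistory

__all__ = [
    "PatientDiseaseMatrix",
    "build_vocabulary",
    "build_matrix",
    "drop_empty_columns",
    "persist_matrix",
    "load_matrix",
    "MatrixIOError",
]


class MatrixIOError(ValueError):
    """Persisted matrix and its sidecar files disagree."""


@dataclass
class PatientDiseaseMatrix:
    """Binary N x M diagnosis matrix with row/column label registries."""

    PD: sp.csr_matrix
    row_ids: list[str]
    col_codes: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.PD = sp.csr_matrix(self.PD, dtype=np.int8)
        n, m = self.PD.shape
        if len(self.row_ids) != n:
            raise ValueError(f"{len(self.row_ids)} row ids for {n} rows")
        if len(self.col_codes) != m:
            raise ValueError(f"{len(self.col_codes)} codes for {m} columns")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} rows")
        if len(set(self.row_ids)) != n or len(set(self.col_codes)) != m:
            raise ValueError("duplicate row ids or column codes")
        if self.PD.nnz and not np.all(self.PD.data == 1):
            raise ValueError("matrix entries must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.PD.shape

    @property
    def labels_array(self) -> np.ndarray:
        return np.asarray(self.labels)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.PD.todense(), dtype=float)

    def equals(self, other: "PatientDiseaseMatrix") -> bool:
        return (
            self.row_ids == other.row_ids
            and self.col_codes == other.col_codes
            and self.labels == other.labels
            and self.shape == other.shape
            and (self.PD != other.PD).nnz == 0
        )


def build_vocabulary(
    histories: Iterable[PatientHistory],
    exclude: Iterable[str] = (),
) -> list[str]:
    """Lexicographically sorted distinct codes over all histories, minus ``exclude``.

    The target disease code is always passed in ``exclude`` by callers: cases
    cannot carry it post-censoring and controls never carry it, so excluding
    it makes that absence structural rather than incidental.
    """
    excluded = set(exclude)
    codes: set[str] = set()
    for h in histories:
        codes.update(h.codes)
    vocab = sorted(codes - excluded)
    if not vocab:
        warnings.warn("empty vocabulary", stacklevel=2)
    return vocab


def build_matrix(
    histories: Sequence[PatientHistory],
    vocab: Sequence[str],
) -> PatientDiseaseMatrix:
    """Build the binary matrix over a fixed vocabulary.

    Codes outside ``vocab`` are ignored (a patient with no in-vocabulary code
    yields an all-zero row), which makes the construction inductive: a test
    patient can be mapped onto a training vocabulary.
    """
    col_index = {code: j for j, code in enumerate(vocab)}
    rows, cols = [], []
    for i, h in enumerate(histories):
        for code in h.codes:
            j = col_index.get(code)
            if j is not None:
                rows.append(i)
                cols.append(j)
    shape = (len(histories), len(vocab))
    pd_mat = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=shape
    )
    return PatientDiseaseMatrix(
        PD=pd_mat,
        row_ids=[h.patient_id for h in histories],
        col_codes=list(vocab),
        labels=[h.label for h in histories],
    )


def drop_empty_columns(pdm: PatientDiseaseMatrix) -> PatientDiseaseMatrix:
    """Drop all-zero columns (they carry no factorization signal) and shrink the vocabulary."""
    col_counts = np.asarray(pdm.PD.sum(axis=0)).ravel()
    keep = np.flatnonzero(col_counts > 0)
    return PatientDiseaseMatrix(
        PD=pdm.PD[:, keep].tocsr(),
        row_ids=list(pdm.row_ids),
        col_codes=[pdm.col_codes[j] for j in keep],
        labels=list(pdm.labels),
    )


def persist_matrix(pdm: PatientDiseaseMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``.rows.txt``, ``.cols.txt``, ``.labels.txt`` sidecars."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix) + ".mtx", pdm.PD.tocoo(), field="integer")
    for suffix, lines in [
        (".rows.txt", pdm.row_ids),
        (".cols.txt", pdm.col_codes),
        (".labels.txt", pdm.labels),
    ]:
        Path(str(prefix) + suffix).write_text(
            "\n".join(lines) + "\n" if lines else "", encoding="utf-8"
        )


def _read_lines(path: Path) -> list[str]:
    text = path.read_text(encoding="utf-8")
    return text.splitlines()


def load_matrix(prefix: str | Path) -> PatientDiseaseMatrix:
    """Load a persisted matrix, verifying sidecar lengths against the MTX shape."""
    prefix = str(prefix)
    pd_mat = sp.csr_matrix(mmread(prefix + ".mtx"))
    row_ids = _read_lines(Path(prefix + ".rows.txt"))
    col_codes = _read_lines(Path(prefix + ".cols.txt"))
    labels = _read_lines(Path(prefix + ".labels.txt"))
    n, m = pd_mat.shape
    if len(row_ids) != n or len(labels) != n:
        raise MatrixIOError(
            f"sidecar rows ({len(row_ids)}) / labels ({len(labels)}) "
            f"do not match matrix rows ({n})"
        )
    if len(col_codes) != m:
        raise MatrixIOError(
            f"sidecar columns ({len(col_codes)}) do not match matrix columns ({m})"
        )
    return PatientDiseaseMatrix(pd_mat, row_ids, col_codes, labels)
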