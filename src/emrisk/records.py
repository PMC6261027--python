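"""Reading, normalization and noise filtering of raw outpatient diagnostic records.

A raw record is one row of a delimited text file: a patient identifier, a
visit date and an ICD-9-CM diagnosis code as written by the coder (possibly
dotted, possibly short). Claims databases store these codes in a canonical
five-character form; ``normalize_icd9`` maps any valid spelling onto it.
``filter_noise`` removes the three classes of noise found in administrative
claims: malformed identifiers/codes, implausible or out-of-window dates, and
garbled content.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "DiagnosticRecord",
    "NoiseReport",
    "ParseWarning",
    "Icd9Error",
    "HEADER",
    "DEFAULT_WINDOW",
    "normalize_icd9",
    "read_diagnostic_records",
    "write_diagnostic_records",
    "filter_noise",
]

HEADER = ("patient_id", "visit_date", "icd9_code")

#: Plausible observation window for the emulated 2000-2008 claims cohort.
DEFAULT_WINDOW = (dt.date(2000, 1, 1), dt.date(2008, 12, 31))

#: Canonical five-character form: 5 digits, or V + 4 digits, or E + 4 digits.
CODE5_RE = re.compile(r"^(?:[0-9]{5}|V[0-9]{4}|E[0-9]{4})$")

_RAW_CODE_RE = re.compile(r"^[0-9VEve.]+$")

RULE_FORMAT = "incorrect_format"
RULE_INCOMPLETE = "missing_or_out_of_window"
RULE_GARBLED = "garbled"
NOISE_RULES = (RULE_FORMAT, RULE_INCOMPLETE, RULE_GARBLED)


class ParseWarning(UserWarning):
    """A row of an input file could not be parsed and was skipped."""


class Icd9Error(ValueError):
    """A diagnosis code cannot be normalized to the five-character form."""


@dataclass(frozen=True)
class DiagnosticRecord:
    """One patient-visit-diagnosis event, the atomic EMR row.

    ``visit_date`` is kept as the string read from the file until the record
    passes noise filtering (an unparseable date is itself a noise condition);
    the :attr:`date` property parses it on demand.
    """

    patient_id: str
    visit_date: str
    code_raw: str
    code5: str | None = None

    @property
    def date(self) -> dt.date | None:
        """The visit date as a ``datetime.date``, or None if unparseable."""
        try:
            return dt.date.fromisoformat(self.visit_date.strip())
        except ValueError:
            return None

    @property
    def code(self) -> str:
        """The normalized code if available, else the raw code."""
        return self.code5 if self.code5 is not None else self.code_raw


@dataclass
class NoiseReport:
    """Accounting of noise filtering: every removal attributed to one rule."""

    n_input: int
    n_removed: int
    removals_by_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_removed != sum(self.removals_by_rule.values()):
            raise ValueError("n_removed must equal the sum of per-rule counts")
        if self.n_removed > self.n_input:
            raise ValueError("cannot remove more records than were input")

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = yaml.safe_dump(
            {
                "n_input": self.n_input,
                "n_removed": self.n_removed,
                "removals_by_rule": dict(self.removals_by_rule),
            },
            sort_keys=False,
        )
        if path is not None:
            Path(path).write_text(doc, encoding="utf-8")
        return doc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NoiseReport":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(data["n_input"], data["n_removed"], data["removals_by_rule"])


def normalize_icd9(code_raw: str) -> str:
    """Normalize an ICD-9-CM code string to its five-character form.

    The integer part is left-padded with zeros (to three digits for numeric
    and E codes, two for V codes, after the letter) and the fractional part is
    right-padded with zeros (to two digits; E codes carry a single fractional
    digit so that the body is four digits). ``"714.0"`` becomes ``"71400"``.
    Undotted inputs are split positionally at the integer-part width.

    Raises :class:`Icd9Error` for empty input, characters outside
    ``[0-9VEve.]``, multiple dots, or too many integer/fractional digits.
    """
    s = code_raw.strip()
    if not s:
        raise Icd9Error("empty code")
    if not _RAW_CODE_RE.match(s):
        raise Icd9Error(f"illegal characters in code {code_raw!r}")
    s = s.upper()
    if s.count(".") > 1:
        raise Icd9Error(f"multiple dots in code {code_raw!r}")

    letter = ""
    if s[0] in "VE":
        letter, s = s[0], s[1:]
    if "V" in s or "E" in s:
        raise Icd9Error(f"letter not in leading position in {code_raw!r}")

    int_width = 2 if letter == "V" else 3
    frac_width = 1 if letter == "E" else 2

    if "." in s:
        head, _, frac = s.partition(".")
    elif len(s) > int_width:
        head, frac = s[:int_width], s[int_width:]
    else:
        head, frac = s, ""

    if not head:
        raise Icd9Error(f"missing integer part in {code_raw!r}")
    if len(head) > int_width or len(frac) > frac_width:
        raise Icd9Error(f"too many digits in {code_raw!r}")

    code5 = letter + head.zfill(int_width) + frac.ljust(frac_width, "0")
    if not CODE5_RE.match(code5):  # pragma: no cover - defensive
        raise Icd9Error(f"normalization produced invalid code {code5!r}")
    return code5


def read_diagnostic_records(
    path: str | Path,
    *,
    delimiter: str = ",",
    header: bool | str = "auto",
) -> list[DiagnosticRecord]:
    """Read diagnostic records from a delimited text file.

    The expected layout is ``patient_id,visit_date,icd9_code`` (UTF-8,
    ISO-8601 dates). With ``header="auto"`` a leading row matching those
    column names is skipped. Rows with a wrong field count are skipped with
    a :class:`ParseWarning`; field values are preserved verbatim.
    """
    records: list[DiagnosticRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for i, row in enumerate(reader):
            if i == 0:
                cells = tuple(c.strip().lower() for c in row)
                if header is True or (header == "auto" and cells == HEADER):
                    continue
            if len(row) != len(HEADER):
                warnings.warn(
                    f"{path}: row {i + 1} has {len(row)} fields, expected "
                    f"{len(HEADER)}; skipped",
                    ParseWarning,
                    stacklevel=2,
                )
                continue
            records.append(DiagnosticRecord(row[0], row[1], row[2]))
    return records


def write_diagnostic_records(
    records: Iterable[DiagnosticRecord], path: str | Path
) -> None:
    """Write records in the canonical dialect, using normalized codes when set."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(HEADER)
        for rec in records:
            writer.writerow([rec.patient_id, rec.visit_date.strip(), rec.code])


def _garbled(*fields: str) -> bool:
    return any(
        not f.strip() or any(not ch.isprintable() for ch in f) for f in fields
    )


def _valid_patient_id(pid: str, length: int | None) -> bool:
    pid = pid.strip()
    if not pid or not pid.isalnum():
        return False
    return length is None or len(pid) == length


def filter_noise(
    records: Sequence[DiagnosticRecord],
    *,
    window: tuple[dt.date, dt.date] | None = DEFAULT_WINDOW,
    id_length: int | None = 10,
) -> tuple[list[DiagnosticRecord], NoiseReport]:
    """Remove the three noise classes and normalize surviving records.

    Rule 1 (``incorrect_format``): unnormalizable diagnosis codes, or patient
    identifiers that are non-alphanumeric or of the wrong length
    (``id_length``; None disables the length check).
    Rule 2 (``missing_or_out_of_window``): unparseable visit dates or dates
    outside the plausible observation ``window`` (None disables).
    Rule 3 (``garbled``): any field empty after stripping or containing
    non-printable characters.

    A record failing several rules is counted once, under the first matching
    rule in the order above; empty or non-printable fields fall through to
    rule 3. Surviving records come back with ``code5`` set and the visit date
    in ISO form; order is preserved.
    """
    counts = {rule: 0 for rule in NOISE_RULES}
    clean: list[DiagnosticRecord] = []
    for rec in records:
        pid, date_s, code_s = rec.patient_id, rec.visit_date, rec.code_raw
        garbled = _garbled(pid, date_s, code_s)

        code5: str | None = None
        format_bad = False
        if not _garbled(pid) and not _valid_patient_id(pid, id_length):
            format_bad = True
        if not _garbled(code_s):
            try:
                code5 = normalize_icd9(code_s)
            except Icd9Error:
                format_bad = True

        date_bad = False
        if not _garbled(date_s):
            d = rec.date
            if d is None:
                date_bad = True
            elif window is not None and not (window[0] <= d <= window[1]):
                date_bad = True

        if format_bad:
            counts[RULE_FORMAT] += 1
        elif date_bad:
            counts[RULE_INCOMPLETE] += 1
        elif garbled:
            counts[RULE_GARBLED] += 1
        else:
            clean.append(
                replace(rec, visit_date=rec.date.isoformat(), code5=code5)
            )

    report = NoiseReport(
        n_input=len(records),
        n_removed=sum(counts.values()),
        removals_by_rule=counts,
    )
    return clean, report
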