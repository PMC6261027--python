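"""Case/control cohort construction with index-date censoring.

A *case* is a patient with at least ``min_dx`` diagnoses of the target code
who also appears in the catastrophic-illness registry; their history is cut
strictly before the first target diagnosis (the index date), so a risk model
only ever sees pre-diagnosis data. A *control* has at least one record in
the observation window and no target-code diagnosis at all. Patients with
target-code evidence below the case threshold are excluded from both arms to
avoid label contamination.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import DEFAULT_WINDOW, DiagnosticRecord

__all__ = [
    "PatientHistory",
    "Cohort",
    "select_cases",
    "select_controls",
    "build_cohort",
    "summarize_cohort",
    "prevalence_percent",
]

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class PatientHistory:
    """A labeled, censored, date-ordered diagnosis history for one patient."""

    patient_id: str
    label: str
    records: tuple[DiagnosticRecord, ...]
    censor_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.label not in (CASE, CONTROL):
            raise ValueError(f"label must be {CASE!r} or {CONTROL!r}")
        if self.label == CASE and self.censor_date is not None:
            if any(r.date >= self.censor_date for r in self.records):
                raise ValueError("case records must predate the censor date")

    @property
    def codes(self) -> set[str]:
        return {r.code for r in self.records}


@dataclass
class Cohort:
    """Both study arms plus the bookkeeping of how they were selected."""

    cases: list[PatientHistory]
    controls: list[PatientHistory]
    target_code: str
    window: tuple[dt.date, dt.date]
    selection_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = {h.patient_id for h in self.cases} & {
            h.patient_id for h in self.controls
        }
        if overlap:
            raise ValueError(f"patients in both arms: {sorted(overlap)[:5]}")

    @property
    def histories(self) -> list[PatientHistory]:
        return list(self.cases) + list(self.controls)

    @property
    def prevalence_percent(self) -> float:
        return prevalence_percent(len(self.cases), len(self.controls))


def prevalence_percent(n_cases: int, n_controls: int) -> float:
    """Cohort prevalence as a percentage, 100·cases/(cases+controls)."""
    total = n_cases + n_controls
    if total == 0:
        raise ValueError("empty cohort")
    return 100.0 * n_cases / total


def _in_window(
    rec: DiagnosticRecord, window: tuple[dt.date, dt.date] | None
) -> bool:
    d = rec.date
    if d is None:
        return False
    return window is None or window[0] <= d <= window[1]


def _by_patient(
    records: Iterable[DiagnosticRecord],
    window: tuple[dt.date, dt.date] | None,
) -> dict[str, list[DiagnosticRecord]]:
    grouped: dict[str, list[DiagnosticRecord]] = {}
    for rec in records:
        if _in_window(rec, window):
            grouped.setdefault(rec.patient_id, []).append(rec)
    for recs in grouped.values():
        recs.sort(key=lambda r: (r.date, r.code))
    return grouped


def select_cases(
    records: Sequence[DiagnosticRecord],
    registry: set[str],
    target_code: str,
    *,
    min_dx: int = 2,
    window: tuple[dt.date, dt.date] | None = DEFAULT_WINDOW,
) -> list[PatientHistory]:
    """Select case histories, censored strictly before the first target diagnosis.

    A patient qualifies iff they have >= ``min_dx`` target-code diagnoses in
    the window AND appear in the registry. The returned history holds all
    non-target records strictly before the earliest target diagnosis, which
    becomes ``censor_date``.
    """
    if not registry:
        warnings.warn("empty registry: no cases can be confirmed", stacklevel=2)
    cases = []
    for pid, recs in sorted(_by_patient(records, window).items()):
        target_dates = sorted(r.date for r in recs if r.code == target_code)
        if len(target_dates) >= min_dx and pid in registry:
            censor = target_dates[0]
            history = tuple(
                r for r in recs if r.code != target_code and r.date < censor
            )
            cases.append(PatientHistory(pid, CASE, history, censor))
    return cases


def select_controls(
    records: Sequence[DiagnosticRecord],
    case_ids: set[str],
    target_code: str,
    *,
    window: tuple[dt.date, dt.date] | None = DEFAULT_WINDOW,
) -> list[PatientHistory]:
    """Select control histories: full-window, no target-code evidence at all.

    Patients with any target diagnosis are excluded even when they fall short
    of the case threshold, so neither arm carries contaminated labels.
    """
    controls = []
    for pid, recs in sorted(_by_patient(records, window).items()):
        if pid in case_ids:
            continue
        if any(r.code == target_code for r in recs):
            continue
        controls.append(PatientHistory(pid, CONTROL, tuple(recs), None))
    return controls


def build_cohort(
    records: Sequence[DiagnosticRecord],
    registry: set[str],
    target_code: str,
    *,
    min_dx: int = 2,
    window: tuple[dt.date, dt.date] | None = DEFAULT_WINDOW,
) -> Cohort:
    """Run case then control selection and log the exclusion flow."""
    grouped = _by_patient(records, window)
    cases = select_cases(
        records, registry, target_code, min_dx=min_dx, window=window
    )
    case_ids = {h.patient_id for h in cases}
    controls = select_controls(records, case_ids, target_code, window=window)
    with_target = {
        pid
        for pid, recs in grouped.items()
        if any(r.code == target_code for r in recs)
    }
    log = {
        "patients_with_records_in_window": len(grouped),
        "patients_with_target_code": len(with_target),
        "cases": len(cases),
        "excluded_subthreshold_or_unregistered": len(with_target) - len(case_ids),
        "controls": len(controls),
    }
    win = window if window is not None else DEFAULT_WINDOW
    return Cohort(cases, controls, target_code, win, log)


def _per_patient_stats(
    histories: Sequence[PatientHistory], years: float
) -> pd.DataFrame:
    rows = [
        {
            "records_per_year": len(h.records) / years,
            "visits_per_year": len({r.date for r in h.records}) / years,
            "distinct_codes": len(h.codes),
        }
        for h in histories
    ]
    return pd.DataFrame(rows)


def summarize_cohort(
    cohort: Cohort,
    *,
    age: Mapping[str, float] | None = None,
    female: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Descriptive per-arm summary with two-sample tests.

    Continuous rows (records/year, visits/year, distinct codes, optionally
    age) report mean and SD per arm with Student's two-sample t statistic;
    the female proportion, when sex is supplied, is compared with Pearson's
    chi-squared on the 2x2 table (no continuity correction). With one arm
    empty the test columns are left as NaN. The result carries the cohort
    prevalence (percent) in ``df.attrs["prevalence_percent"]``.
    """
    years = max((cohort.window[1] - cohort.window[0]).days / 365.25, 1e-9)
    arms = {CASE: cohort.cases, CONTROL: cohort.controls}
    stats_by_arm = {
        arm: _per_patient_stats(hs, years) for arm, hs in arms.items()
    }
    both = all(len(hs) > 0 for hs in arms.values())

    rows = {}
    continuous = ["records_per_year", "visits_per_year", "distinct_codes"]
    for name in continuous:
        row = {}
        for arm in (CASE, CONTROL):
            vals = stats_by_arm[arm].get(name, pd.Series(dtype=float))
            row[f"{arm}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{arm}_sd"] = vals.std(ddof=0) if len(vals) else np.nan
        if both:
            t, p = stats.ttest_ind(
                stats_by_arm[CASE][name], stats_by_arm[CONTROL][name]
            )
            row["statistic"], row["p_value"] = float(t), float(p)
        else:
            row["statistic"] = row["p_value"] = np.nan
        rows[name] = row

    if age is not None:
        vals = {
            arm: np.array(
                [age[h.patient_id] for h in hs if h.patient_id in age], float
            )
            for arm, hs in arms.items()
        }
        row = {}
        for arm in (CASE, CONTROL):
            row[f"{arm}_mean"] = vals[arm].mean() if vals[arm].size else np.nan
            row[f"{arm}_sd"] = vals[arm].std() if vals[arm].size else np.nan
        if all(v.size > 1 for v in vals.values()):
            t, p = stats.ttest_ind(vals[CASE], vals[CONTROL])
            row["statistic"], row["p_value"] = float(t), float(p)
        else:
            row["statistic"] = row["p_value"] = np.nan
        rows["age"] = row

    if female is not None:
        counts = {}
        for arm, hs in arms.items():
            flags = [female[h.patient_id] for h in hs if h.patient_id in female]
            counts[arm] = (sum(flags), len(flags) - sum(flags))
        row = {
            "case_mean": counts[CASE][0] / max(sum(counts[CASE]), 1),
            "case_sd": np.nan,
            "control_mean": counts[CONTROL][0] / max(sum(counts[CONTROL]), 1),
            "control_sd": np.nan,
        }
        table = np.array([counts[CASE], counts[CONTROL]])
        if both and table.sum(axis=0).min() > 0:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            row["statistic"], row["p_value"] = float(chi2), float(p)
        else:
            row["statistic"] = row["p_value"] = np.nan
        rows["female_proportion"] = row

    df = pd.DataFrame(rows).T
    df.attrs["prevalence_percent"] = (
        cohort.prevalence_percent if (cohort.cases or cohort.controls) else np.nan
    )
    df.attrs["n_cases"] = len(cohort.cases)
    df.attrs["n_controls"] = len(cohort.controls)
    return df
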