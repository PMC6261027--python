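"""Synthetic longitudinal EMR cohorts with planted latent-factor structure.

Real national claims cohorts are access-restricted, so the pipeline is
exercised on generated data whose ground truth is known. The generative
model mirrors the assumptions of the analysis: each patient mixes k latent
disease themes; a designated subset of themes is *risk-enriched* — future
cases load ``case_theme_boost`` times more heavily on them. A patient's
binary diagnosis profile arises from the nonnegative low-rank intensity
``lambda = true_PR . true_DR^T`` through a Bernoulli link
``P(v_nm = 1) = 1 - exp(-lambda_nm)``, which keeps the matrix binary while
preserving approximate low-rank structure. The profile is then expanded
into dated visit records over a 2000-2008-style window; cases additionally
receive >= 2 target-code diagnoses dated after all their other records, so
censoring at the first target diagnosis recovers exactly the planted
profile. Malformed records (bad identifiers, garbled codes, out-of-window
dates) are injected at a configurable rate to exercise noise filtering.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .records import DEFAULT_WINDOW

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "planted_factor_matrix",
    "generate_synthetic_emr",
]


@dataclass
class SyntheticConfig:
    """Generation parameters; the defaults emulate a balanced 500/500 study sample.

    ``n_cases``/``n_controls`` default to the balanced design used for rank
    selection; set them to e.g. 10/9990 to emulate the source cohort's 0.1%
    prevalence. ``theme_code_sparsity`` is the fraction of the M codes active
    in each theme; ``case_theme_boost`` multiplies case loadings on the
    ``n_risk_themes`` designated risk themes (1.0 gives an exchangeable null
    cohort). ``noise_rate`` is the fraction of extra malformed records
    appended to the clean stream.
    """

    n_cases: int = 500
    n_controls: int = 500
    vocab_size: int = 400
    k_themes: int = 5
    n_risk_themes: int = 2
    theme_code_sparsity: float = 0.05
    background_rate: float = 0.02
    case_theme_boost: float = 3.0
    visits_per_year_mean: float = 6.0
    years: int = 9
    noise_rate: float = 0.02
    registry_false_entry_rate: float = 0.0
    target_code: str = "71400"
    window: tuple[dt.date, dt.date] = DEFAULT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cases, self.n_controls, self.vocab_size, self.k_themes,
            self.n_risk_themes, self.years,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        for name in ("theme_code_sparsity", "background_rate", "noise_rate",
                     "registry_false_entry_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1]")
        if self.case_theme_boost < 1.0:
            raise ValueError("case_theme_boost must be >= 1")
        if self.k_themes >= self.vocab_size:
            raise ValueError("k_themes must be below vocab_size")
        if self.n_risk_themes > self.k_themes:
            raise ValueError("n_risk_themes cannot exceed k_themes")
        if max(1, round(self.theme_code_sparsity * self.vocab_size)) < 1:
            raise ValueError("each theme must activate at least one code")

    @property
    def n_patients(self) -> int:
        return self.n_cases + self.n_controls

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "window" in data:
            lo, hi = data["window"]
            data["window"] = (
                dt.date.fromisoformat(str(lo)), dt.date.fromisoformat(str(hi))
            )
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    true_PR: np.ndarray  # N x k patient theme weights
    true_DR: np.ndarray  # M x k theme code loadings
    risk_theme_index: list[int]
    labels: list[str]  # per patient, aligned with true_PR rows
    patient_ids: list[str]
    codes: list[str]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "true_PR.csv", self.true_PR, delimiter=",")
        np.savetxt(out / "true_DR.csv", self.true_DR, delimiter=",")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "risk_theme_index": self.risk_theme_index,
                    "labels": self.labels,
                    "patient_ids": self.patient_ids,
                    "codes": self.codes,
                },
                indent=1,
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, in_dir: str | Path) -> "SyntheticTruth":
        src = Path(in_dir)
        meta = json.loads((src / "truth.json").read_text(encoding="utf-8"))
        return cls(
            true_PR=np.loadtxt(src / "true_PR.csv", delimiter=",", ndmin=2),
            true_DR=np.loadtxt(src / "true_DR.csv", delimiter=",", ndmin=2),
            risk_theme_index=meta["risk_theme_index"],
            labels=meta["labels"],
            patient_ids=meta["patient_ids"],
            codes=meta["codes"],
        )


def _code_pool(config: SyntheticConfig) -> list[str]:
    """Valid five-digit numeric codes, excluding the target code."""
    codes = []
    v = 100
    while len(codes) < config.vocab_size:
        code = f"{v:05d}"
        if code != config.target_code:
            codes.append(code)
        v += 7  # stride spreads codes over the numeric range
    return codes


def _patient_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    case_ids = [f"A{i:09d}" for i in range(config.n_cases)]
    control_ids = [f"B{i:09d}" for i in range(config.n_controls)]
    return case_ids, control_ids


def planted_factor_matrix(
    config: SyntheticConfig,
    *,
    bernoulli: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Draw a binary patient-disease matrix from planted low-rank structure.

    Theme loadings ``true_DR`` activate about ``theme_code_sparsity * M``
    codes each with Uniform(0.5, 1.5) weights; patient weights ``true_PR``
    are Gamma(4, 0.15), with case rows multiplied by ``case_theme_boost`` on
    the risk themes. The Bernoulli step adds ``background_rate`` to the
    intensity so incidental, theme-free diagnoses occur on every code. Rows
    are ordered cases first, then controls. With ``bernoulli=False`` the
    exact nonnegative product ``true_PR.true_DR^T`` is returned instead of
    its Bernoulli realization (no background; useful for exact-rank
    recovery checks).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m, k = config.n_patients, config.vocab_size, config.k_themes
    n_active = max(1, round(config.theme_code_sparsity * m))

    true_DR = np.zeros((m, k))
    for t in range(k):
        active = rng.choice(m, size=n_active, replace=False)
        true_DR[active, t] = rng.uniform(0.5, 1.5, size=n_active)
    if not np.all(true_DR.sum(axis=0) > 0):  # pragma: no cover - defensive
        raise ValueError("degenerate configuration: a theme has no codes")

    # shape 4 keeps per-patient theme propensities moderately heterogeneous:
    # the log-scale spread (~0.53) leaves a boost of 3 (log-separation ~1.1)
    # recoverable, while mean 0.6 yields ~10% matrix density
    true_PR = rng.gamma(shape=4.0, scale=0.15, size=(n, k))
    risk_themes = list(range(config.n_risk_themes))
    labels = ["case"] * config.n_cases + ["control"] * config.n_controls
    true_PR[: config.n_cases, risk_themes] *= config.case_theme_boost

    intensity = true_PR @ true_DR.T
    if bernoulli:
        # background_rate adds theme-free incidental diagnoses, so any code
        # can occur; the exact product below stays strictly rank-k
        prob = 1.0 - np.exp(-(intensity + config.background_rate))
        PD = (rng.random((n, m)) < prob).astype(np.int8)
        # cohort members have at least one diagnosis by definition; give an
        # empty profile one code drawn from its own intensity profile
        for i in np.flatnonzero(PD.sum(axis=1) == 0):
            p = prob[i] / prob[i].sum()
            PD[i, rng.choice(m, p=p)] = 1
    else:
        PD = intensity
    case_ids, control_ids = _patient_ids(config)
    truth = SyntheticTruth(
        true_PR=true_PR,
        true_DR=true_DR,
        risk_theme_index=risk_themes,
        labels=labels,
        patient_ids=case_ids + control_ids,
        codes=_code_pool(config),
    )
    return PD, truth


def _dotted(code5: str) -> str:
    """Write a five-digit numeric code in its dotted claims spelling."""
    return f"{code5[:3]}.{code5[3:]}"


def _random_dates(
    rng: np.random.Generator,
    lo: dt.date,
    hi: dt.date,
    size: int,
) -> list[dt.date]:
    span = (hi - lo).days
    offsets = rng.integers(0, span + 1, size=size)
    return [lo + dt.timedelta(days=int(o)) for o in offsets]


def generate_synthetic_emr(
    config: SyntheticConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Generate a records CSV, a registry file and a ground-truth archive.

    Every active code in a patient's planted profile produces at least one
    dated visit record. Case records are dated strictly before the case's
    first target-code diagnosis; two target-code records are placed at and
    after that index date, so cohort selection (>= 2 target diagnoses plus
    registry membership, censor at the first) reconstructs exactly the
    planted profile. Controls carry no target code. Noise records are
    appended at ``noise_rate`` (relative to the clean record count) cycling
    through the three noise classes. Returns the written paths.
    """
    rng = np.random.default_rng(config.seed)
    PD, truth = planted_factor_matrix(config, rng=rng)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lo, hi = config.window
    span_days = (hi - lo).days

    rows: list[tuple[str, str, str]] = []
    for i, pid in enumerate(truth.patient_ids):
        is_case = truth.labels[i] == "case"
        active = np.flatnonzero(PD[i])
        if is_case:
            # index date in the back half of the window; history strictly before
            index_offset = int(rng.integers(span_days // 2, span_days))
            index_date = lo + dt.timedelta(days=index_offset)
            hist_hi = index_date - dt.timedelta(days=1)
        else:
            index_date = None
            hist_hi = hi

        n_visits = max(
            1, int(rng.poisson(config.visits_per_year_mean * config.years))
        )
        visit_dates = _random_dates(rng, lo, hist_hi, n_visits)
        for j in active:
            date = visit_dates[int(rng.integers(len(visit_dates)))]
            rows.append((pid, date.isoformat(), _dotted(truth.codes[j])))
        if is_case:
            second = index_date + dt.timedelta(
                days=int(rng.integers(1, max(2, (hi - index_date).days + 1)))
            )
            second = min(second, hi)
            for d in (index_date, second):
                rows.append((pid, d.isoformat(), _dotted(config.target_code)))

    n_noise = round(config.noise_rate * len(rows))
    noise_makers = [
        lambda r: ("BAD", "2004-06-15", "250.0"),  # wrong ID length
        lambda r: (f"C{int(r.integers(0, 10**9)):09d}", "2004-06-15", "##!@"),
        lambda r: (f"C{int(r.integers(0, 10**9)):09d}", "1899-01-01", "401.1"),
    ]
    for i in range(n_noise):
        pid, date, code = noise_makers[i % len(noise_makers)](rng)
        rows.append((str(pid), str(date), str(code)))
    order = rng.permutation(len(rows))
    rows = [rows[int(i)] for i in order]

    records_path = out / "records.csv"
    with open(records_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("patient_id,visit_date,icd9_code\n")
        for pid, date, code in rows:
            fh.write(f"{pid},{date},{code}\n")

    case_ids = [
        pid for pid, lab in zip(truth.patient_ids, truth.labels)
        if lab == "case"
    ]
    registry = list(case_ids)
    n_false = round(config.registry_false_entry_rate * len(case_ids))
    if n_false:
        control_ids = [
            pid for pid, lab in zip(truth.patient_ids, truth.labels)
            if lab == "control"
        ]
        false_ids = rng.choice(control_ids, size=n_false, replace=False)
        registry.extend(str(x) for x in false_ids)
    registry_path = out / "registry.txt"
    registry_path.write_text("\n".join(registry) + "\n", encoding="utf-8")

    truth_dir = out / "truth"
    truth.save(truth_dir)
    return {
        "records": records_path,
        "registry": registry_path,
        "truth": truth_dir,
    }
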