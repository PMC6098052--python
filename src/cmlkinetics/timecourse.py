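"""Patient time-course data model, cohort I/O and the selection filters.

BCR-ABL transcript levels are stored as percent on the international scale
(IS); the working quantity throughout the package is
``LRATIO = log10(BCR-ABL/ABL in %)``.  Values below the assay's
quantification limit (QL) are left-censored: the stored number is the QL
itself and a flag marks the row, so that the censoring flag (not the stored
value) drives any likelihood downstream.

Patient selection mirrors the clinical analysis protocol:

* *statistics filter* (criteria 1-5): enough points, early points for the
  initial slope, a baseline measurement, minimal follow-up, no long gaps;
* *model filter* (criterion 6): a genuinely biphasic decline,
  ``alpha > beta > 0``;
* *prediction filter* (criterion 7): complete five-year follow-up.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .config import load_defaults

ARMS = ("imatinib", "dasatinib")

COHORT_COLUMNS = ["patient_id", "arm", "time_months", "ratio_percent", "censored"]


class CohortFormatError(ValueError):
    """Raised for malformed cohort files (missing column, bad row, ...)."""


@dataclass(frozen=True)
class Measurement:
    """One RQ-PCR measurement.

    time is months since treatment start; ratio_percent is BCR-ABL/ABL in %
    IS (equal to the QL when censored); weight in [0, 1] supports the
    robustness reanalysis (down-weighting high ratios).
    """

    time: float
    ratio_percent: float
    censored: bool = False
    weight: float = 1.0

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"measurement time must be >= 0, got {self.time}")
        if self.ratio_percent <= 0:
            raise ValueError("ratio_percent must be positive")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


@dataclass
class PatientTimeCourse:
    patient_id: str
    arm: str
    measurements: list[Measurement]
    ql_percent: float

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.ql_percent <= 0:
            raise ValueError("ql_percent must be positive")
        if not self.measurements:
            raise ValueError("a patient needs at least one measurement")
        times = [m.time for m in self.measurements]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("measurement times must be strictly increasing")
        for m in self.measurements:
            if m.censored and m.ratio_percent != self.ql_percent:
                raise ValueError(
                    "censored measurements must store the QL value "
                    f"({self.ql_percent}), got {m.ratio_percent}"
                )

    @property
    def times(self) -> list[float]:
        return [m.time for m in self.measurements]

    @property
    def last_time(self) -> float:
        return self.measurements[-1].time


@dataclass
class Cohort:
    patients: list[PatientTimeCourse]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def by_id(self, patient_id: str) -> PatientTimeCourse:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass
class FilterReport:
    """Outcome of applying selection criteria to a cohort."""

    retained_ids: list[str]
    excluded: dict[str, list[int]]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"patient_id": pid, "retained": 1, "failed_criteria": ""}
                for pid in self.retained_ids]
        rows += [{"patient_id": pid, "retained": 0,
                  "failed_criteria": ";".join(str(c) for c in crits)}
                 for pid, crits in self.excluded.items()]
        return pd.DataFrame(rows, columns=["patient_id", "retained", "failed_criteria"])


def to_lratio(ratio_percent: float) -> float:
    """log10 of a BCR-ABL/ABL value already expressed in percent IS."""
    if ratio_percent <= 0:
        raise ValueError(f"ratio_percent must be > 0, got {ratio_percent}")
    return math.log10(ratio_percent)


def read_cohort(path, ql_percent: float) -> Cohort:
    """Read a cohort CSV (patient_id, arm, time_months, ratio_percent,
    censored[, weight]); censored rows are coerced to the QL value."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:  # noqa: BLE001 - reported as format error
        raise CohortFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    for col in ("time_months", "ratio_percent", "weight"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise CohortFormatError(f"{path}: non-numeric {col} in row {row}")
        df[col] = vals
    dup = df.duplicated(subset=["patient_id", "time_months"])
    if dup.any():
        row = int(dup.idxmax())
        raise CohortFormatError(
            f"{path}: duplicate (patient_id, time_months) in row {row}")
    patients = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_months")
        arm = grp["arm"].iloc[0]
        meas = [
            Measurement(
                time=float(r.time_months),
                ratio_percent=ql_percent if bool(r.censored) else float(r.ratio_percent),
                censored=bool(r.censored),
                weight=float(r.weight),
            )
            for r in grp.itertuples()
        ]
        patients.append(PatientTimeCourse(str(pid), str(arm), meas, ql_percent))
    meta = {"ql_percent": repr(float(ql_percent))}
    return Cohort(patients, meta)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV; ``read_cohort`` round-trips it field-for-field."""
    rows = []
    for p in cohort:
        for m in p.measurements:
            rows.append({
                "patient_id": p.patient_id,
                "arm": p.arm,
                "time_months": f"{m.time:.17g}",
                "ratio_percent": f"{m.ratio_percent:.17g}",
                "censored": int(m.censored),
                "weight": f"{m.weight:.17g}",
            })
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS + ["weight"])
    df.to_csv(path, index=False)


def statistics_filter(patient: PatientTimeCourse, defaults: dict | None = None) -> list[int]:
    """Return the sorted list of violated criteria among 1..5 (empty = pass)."""
    cfg = (defaults or load_defaults())["filters"]
    times = patient.times
    failed = []
    if len(times) < cfg["min_timepoints"]:
        failed.append(1)
    if sum(t <= cfg["early_window_months"] for t in times) < cfg["min_early_measurements"]:
        failed.append(2)
    if times[0] > cfg["first_measurement_max_month"]:
        failed.append(3)
    if times[-1] < cfg["min_followup_months"]:
        failed.append(4)
    if any(b - a > cfg["max_gap_months"] for a, b in zip(times, times[1:])):
        failed.append(5)
    return failed


def model_filter(fit) -> bool:
    """Criterion 6: biphasic decline, alpha > beta > 0 (on a converged fit)."""
    p = fit.params if hasattr(fit, "params") else fit
    return p.alpha > p.beta > 0.0


def prediction_filter(patient: PatientTimeCourse,
                      tolerance_months: float | None = None,
                      defaults: dict | None = None) -> bool:
    """Criterion 7: complete five-year follow-up, within a schedule-jitter
    tolerance (default half the sparse visit interval)."""
    cfg = (defaults or load_defaults())["filters"]
    tol = cfg["prediction_tolerance_months"] if tolerance_months is None else tolerance_months
    return patient.last_time >= cfg["prediction_followup_months"] - tol


def apply_statistics_filter(cohort: Cohort, defaults: dict | None = None) -> FilterReport:
    defaults = defaults or load_defaults()
    retained, excluded = [], {}
    for p in cohort:
        failed = statistics_filter(p, defaults)
        if failed:
            excluded[p.patient_id] = failed
        else:
            retained.append(p.patient_id)
    return FilterReport(retained, excluded)


def apply_weights(patient: PatientTimeCourse, mode: str = "none",
                  threshold_percent: float = 10.0) -> PatientTimeCourse:
    """Robustness reanalysis: down-weight (or drop) measurements whose ratio
    exceeds *threshold_percent* (uncertainty of the ABL reference gene at
    high tumor load).  Returns a new patient; 'none' returns the input."""
    if mode == "none":
        return patient
    if mode not in ("halve", "omit"):
        raise ValueError(f"unknown robustness mode {mode!r}")
    factor = 0.5 if mode == "halve" else 0.0
    meas = [
        Measurement(m.time, m.ratio_percent, m.censored,
                    m.weight * factor if m.ratio_percent > threshold_percent else m.weight)
        for m in patient.measurements
    ]
    return PatientTimeCourse(patient.patient_id, patient.arm, meas, patient.ql_percent)
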