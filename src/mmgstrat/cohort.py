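"""Domain types and CSV ingestion for decompression cohorts.

A cohort couples two tables: a nerve-level table of intraoperative
mechanomyography (MMG) stimulation thresholds recorded before and after
nerve-root decompression, and a patient-level table of Numeric Pain Scale
(NPS) scores at baseline and six weeks.  Thresholds are the lowest current
(mA) evoking a detectable muscle response; stimulation protocols start at
1 mA and step in 1 mA increments, so clinical datasets carry integer values,
but decimals are accepted (literature-derived tables report averaged
thresholds) and non-integrality is only a validation warning.

Parsing is strict about linkage: every nerve row must join to exactly one
patient and every patient must own at least one nerve, because all derived
metrics are patient-anchored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: Physiologic reference threshold (mA): stimulation thresholds at or below
#: this value are considered normal nerve function.
REFERENCE_MA = 2.0

NERVE_COLUMNS = ("patient_id", "nerve_label", "pre_mA", "post_mA")
PATIENT_COLUMNS = ("patient_id", "region", "nps_pre", "nps_6wk")

Region = Literal["lumbar", "cervical"]
Aggregation = Literal["mean", "index", "worst"]


class CohortError(ValueError):
    """Base class for cohort construction and parsing failures."""


class SchemaError(CohortError):
    """A required column is missing or a categorical value is unrecognized."""


class ParseError(CohortError):
    """A cell could not be converted to the expected type."""


class JoinError(CohortError):
    """Nerve and patient tables do not link one-to-many as required."""


@dataclass(frozen=True)
class NerveMeasurement:
    """Pre/post decompression stimulation thresholds for one nerve root.

    Thresholds are in milliamperes and must be >= 1 (stimulation begins at
    1 mA).  A post threshold above the pre threshold ("worsening") is legal
    here and flagged downstream by :func:`validate_cohort`.
    """

    patient_id: str
    nerve_label: str
    pre_mA: float
    post_mA: float

    def __post_init__(self) -> None:
        for name in ("pre_mA", "post_mA"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise CohortError(f"{name} must be finite, got {v!r}")
            if v < 1.0:
                raise CohortError(
                    f"{name} must be >= 1 mA (stimulation floor), got {v!r}"
                )


@dataclass(frozen=True)
class PatientRecord:
    """One patient: region, pain scores, and their ordered nerve measurements.

    Nerve ordering is preserved exactly as read, because index/worst nerve
    selection breaks ties by first occurrence.
    """

    patient_id: str
    region: Region
    nps_pre: int
    nps_6wk: int
    nerves: tuple[NerveMeasurement, ...]

    def __post_init__(self) -> None:
        if self.region not in ("lumbar", "cervical"):
            raise SchemaError(f"unknown region {self.region!r}")
        for name in ("nps_pre", "nps_6wk"):
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= 10:
                raise CohortError(f"{name} must be an integer in [0, 10], got {v!r}")
        if len(self.nerves) == 0:
            raise JoinError(f"patient {self.patient_id!r} has no nerve measurements")
        for nerve in self.nerves:
            if nerve.patient_id != self.patient_id:
                raise JoinError(
                    f"nerve for {nerve.patient_id!r} attached to patient "
                    f"{self.patient_id!r}"
                )

    @property
    def n_nerves(self) -> int:
        return len(self.nerves)


@dataclass(frozen=True)
class MetricConfig:
    """Knobs of the threshold-anchored metric layer.

    reference_mA
        Physiologic reference threshold; elevation is measured above it.
    aggregation
        How multiple nerves summarize to one patient: ``mean`` of thresholds,
        ``index`` nerve (highest pre), or ``worst`` nerve (highest post).
    mcid_points / mcid_fraction
        Minimal clinically important difference rule: an NPS reduction of at
        least ``mcid_points`` OR an improvement fraction of at least
        ``mcid_fraction``.
    min_improvement_mA
        A nerve counts as improved when its threshold drops by at least this.
    """

    reference_mA: float = REFERENCE_MA
    aggregation: Aggregation = "mean"
    mcid_points: int = 2
    mcid_fraction: float = 0.30
    min_improvement_mA: float = 1.0

    def __post_init__(self) -> None:
        if not self.reference_mA > 0:
            raise CohortError("reference_mA must be positive")
        if not 0 < self.mcid_fraction < 1:
            raise CohortError("mcid_fraction must lie in (0, 1)")
        if self.aggregation not in ("mean", "index", "worst"):
            raise CohortError(f"unknown aggregation {self.aggregation!r}")


@dataclass(frozen=True)
class Cohort:
    """A validated set of patients with linked nerve measurements."""

    patients: tuple[PatientRecord, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise JoinError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_nerves(self) -> int:
        return sum(p.n_nerves for p in self.patients)

    def nerves(self) -> Iterator[NerveMeasurement]:
        for p in self.patients:
            yield from p.nerves


@dataclass(frozen=True)
class Anomaly:
    """Advisory finding from :func:`validate_cohort` (never a rejection)."""

    kind: str  # worsening | non_integer | zero_baseline | implausible
    patient_id: str
    nerve_label: str | None
    detail: str


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s: ignoring unknown column(s) %s", path, extra)


def _numeric(df: pd.DataFrame, column: str, path: str) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce")
    bad = out.isna() & df[column].notna()
    if bad.any():
        # +2: header line plus 1-based numbering
        row = int(bad.idxmax()) + 2
        raise ParseError(
            f"{path}: non-numeric value {df[column][bad.idxmax()]!r} in "
            f"column {column!r} at line {row}"
        )
    return out


def read_cohort(nerve_csv_path: str, patient_csv_path: str) -> Cohort:
    """Parse and cross-link the two cohort CSVs into a validated :class:`Cohort`.

    Patients whose pain scores are missing are dropped with a logged
    exclusion (no imputation).  Orphan nerve rows — and patients left with no
    nerves — raise :class:`JoinError`, because every metric is
    patient-anchored.
    """
    nerves_df = pd.read_csv(nerve_csv_path, dtype=str, skipinitialspace=True)
    patients_df = pd.read_csv(patient_csv_path, dtype=str, skipinitialspace=True)
    _require_columns(nerves_df, NERVE_COLUMNS, str(nerve_csv_path))
    _require_columns(patients_df, PATIENT_COLUMNS, str(patient_csv_path))

    pre = _numeric(nerves_df, "pre_mA", str(nerve_csv_path))
    post = _numeric(nerves_df, "post_mA", str(nerve_csv_path))

    missing_pain = patients_df["nps_pre"].isna() | patients_df["nps_6wk"].isna()
    excluded_ids: set[str] = set()
    if missing_pain.any():
        dropped = patients_df.loc[missing_pain, "patient_id"].tolist()
        log.warning(
            "excluding %d patient(s) with missing pain scores: %s",
            len(dropped), dropped,
        )
        excluded_ids = {str(v) for v in dropped}
        patients_df = patients_df.loc[~missing_pain]

    nps_pre = _numeric(patients_df, "nps_pre", str(patient_csv_path))
    nps_6wk = _numeric(patients_df, "nps_6wk", str(patient_csv_path))

    nerves_by_patient: dict[str, list[NerveMeasurement]] = {}
    for i in nerves_df.index:
        pid = str(nerves_df.at[i, "patient_id"])
        nerves_by_patient.setdefault(pid, []).append(
            NerveMeasurement(
                patient_id=pid,
                nerve_label=str(nerves_df.at[i, "nerve_label"]),
                pre_mA=float(pre[i]),
                post_mA=float(post[i]),
            )
        )

    patient_ids = [str(v) for v in patients_df["patient_id"]]
    for pid in excluded_ids:  # nerves of excluded patients leave with them
        nerves_by_patient.pop(pid, None)
    orphans = sorted(set(nerves_by_patient) - set(patient_ids))
    if orphans:
        raise JoinError(f"nerve rows reference unknown patient id(s): {orphans}")
    childless = [pid for pid in patient_ids if pid not in nerves_by_patient]
    if childless:
        raise JoinError(f"patient(s) without any nerve rows: {childless}")

    patients = []
    for pid, idx in zip(patient_ids, patients_df.index):
        region = str(patients_df.at[idx, "region"]).strip().lower()
        patients.append(
            PatientRecord(
                patient_id=pid,
                region=region,  # type: ignore[arg-type]
                nps_pre=int(nps_pre[idx]),
                nps_6wk=int(nps_6wk[idx]),
                nerves=tuple(nerves_by_patient[pid]),
            )
        )

    provenance = {
        "nerve_csv": str(nerve_csv_path),
        "patient_csv": str(patient_csv_path),
        "n_nerve_rows": int(len(nerves_df)),
        "n_patient_rows": int(len(patients_df)),
    }
    return Cohort(patients=tuple(patients), provenance=provenance)


def write_cohort(cohort: Cohort, nerve_csv_path: str, patient_csv_path: str) -> None:
    """Emit the two CSVs with the canonical schemas (round-trips bit-exactly
    for integer thresholds and pain scores)."""

    def _fmt(v: float) -> object:
        return int(v) if float(v).is_integer() else v

    nerve_rows = [
        {
            "patient_id": nv.patient_id,
            "nerve_label": nv.nerve_label,
            "pre_mA": _fmt(nv.pre_mA),
            "post_mA": _fmt(nv.post_mA),
        }
        for nv in cohort.nerves()
    ]
    patient_rows = [
        {
            "patient_id": p.patient_id,
            "region": p.region,
            "nps_pre": p.nps_pre,
            "nps_6wk": p.nps_6wk,
        }
        for p in cohort.patients
    ]
    pd.DataFrame(nerve_rows, columns=list(NERVE_COLUMNS)).to_csv(
        nerve_csv_path, index=False
    )
    pd.DataFrame(patient_rows, columns=list(PATIENT_COLUMNS)).to_csv(
        patient_csv_path, index=False
    )


def validate_cohort(
    cohort: Cohort, reference_mA: float = REFERENCE_MA, implausible_mA: float = 30.0
) -> list[Anomaly]:
    """Screen a parsed cohort for advisory anomalies.

    Returns structured reports for: threshold worsening (post > pre, which
    the measurement protocol should not produce), non-integer thresholds
    (the protocol stimulates in 1 mA increments), zero-baseline pain
    (excluded from improvement analyses downstream), and implausibly high
    thresholds.  Never raises: the cohort stays usable.
    """
    anomalies: list[Anomaly] = []
    for p in cohort.patients:
        if p.nps_pre == 0:
            anomalies.append(
                Anomaly(
                    kind="zero_baseline",
                    patient_id=p.patient_id,
                    nerve_label=None,
                    detail="baseline NPS = 0; improvement fraction undefined",
                )
            )
        for nv in p.nerves:
            if nv.post_mA > nv.pre_mA:
                anomalies.append(
                    Anomaly(
                        kind="worsening",
                        patient_id=p.patient_id,
                        nerve_label=nv.nerve_label,
                        detail=f"threshold worsened {nv.pre_mA:g} -> {nv.post_mA:g} mA",
                    )
                )
            for name, v in (("pre_mA", nv.pre_mA), ("post_mA", nv.post_mA)):
                if not float(v).is_integer():
                    anomalies.append(
                        Anomaly(
                            kind="non_integer",
                            patient_id=p.patient_id,
                            nerve_label=nv.nerve_label,
                            detail=f"{name} = {v:g} is not an integer mA step",
                        )
                    )
                if v > implausible_mA:
                    anomalies.append(
                        Anomaly(
                            kind="implausible",
                            patient_id=p.patient_id,
                            nerve_label=nv.nerve_label,
                            detail=f"{name} = {v:g} mA exceeds {implausible_mA:g} mA",
                        )
                    )
    return anomalies
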