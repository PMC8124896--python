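"""Patient data model for resected pancreatic neuroendocrine tumor (pNET) cohorts.

A cohort is a list of :class:`PatientRecord` objects, one per patient who
underwent curative-intent resection.  Endpoints follow the usual clinical
conventions: recurrence-free survival (RFS) runs from surgery to first
detected recurrence, post-recurrence survival (PRS) from recurrence to death
or last follow-up, and overall survival (OS) is carried as a separate field
anchored at surgery.  Any field may be missing (``None``); analyses are
complete-case per variable.

This module owns eligibility filtering, recurrence-pattern classification,
and early/late recurrence labelling relative to a months cut-off.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "PatientRecord",
    "ExclusionLog",
    "ERStatus",
    "CohortValidationError",
    "apply_eligibility_filters",
    "classify_recurrence_pattern",
    "classify_er_status",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
    "frame_to_records",
]

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

SEXES = frozenset({"male", "female"})
ASA_CLASSES = frozenset({"I", "II", "III", "IV"})
LOCATIONS = frozenset({"head", "body", "tail"})
RESECTION_TYPES = frozenset(
    {"pancreatoduodenectomy", "distal_pancreatectomy", "enucleation_central"}
)
GRADES = frozenset({"G1", "G2", "G3"})
MARGINS = frozenset({"R0", "R1", "R2"})
T_STAGES = frozenset({"T1", "T2", "T3", "T4"})
ERAS = frozenset({"1998-2005", "2006-2010", "2011-2016", "2017-2018"})

#: Sites that count as local disease: remnant gland, transection surface,
#: regional nodes.  Everything else (liver, other organs) is distant.
LOCAL_SITES = frozenset({"remnant_pancreas", "cut_surface", "peripancreatic_nodes"})
DISTANT_SITES = frozenset({"liver", "other_organ"})
RECURRENCE_SITES = LOCAL_SITES | DISTANT_SITES

#: Recurrence-pattern labels (mutually exclusive).
LOCAL = "local"
DISTANT = "distant"
LOCAL_AND_DISTANT = "local_and_distant"
PATTERNS = (LOCAL, DISTANT, LOCAL_AND_DISTANT)

#: Exclusion reason codes, in precedence order.  A record failing several
#: criteria is logged once, under the first failing reason in this order.
EXCLUSION_REASONS = (
    "grade3",
    "genetic_syndrome",
    "r2_resection",
    "synchronous_metastases",
    "missing_recurrence_status",
    "recurrence_lt_3mo",
)

#: Recurrences within this window after surgery are treated as undetected
#: synchronous disease / grossly incomplete resection and excluded.
MIN_RFS_MONTHS = 3.0


class CohortValidationError(ValueError):
    """A record carries a value outside its declared vocabulary or range."""


@dataclass
class PatientRecord:
    """One resected-pNET patient: covariates, endpoints, recurrence sites.

    All fields except ``patient_id`` are optional; ``None`` means missing.
    Times are months from surgery except ``prs_months`` which is months from
    recurrence.
    """

    patient_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    bmi: Optional[float] = None
    asa: Optional[str] = None
    functional: Optional[bool] = None
    symptomatic: Optional[bool] = None
    tumor_size: Optional[float] = None
    location: Optional[str] = None
    multifocal: Optional[bool] = None
    resection_type: Optional[str] = None
    vascular_resection: Optional[bool] = None
    severe_complication: Optional[bool] = None
    grade: Optional[str] = None
    lvi: Optional[bool] = None
    pni: Optional[bool] = None
    margin: Optional[str] = None
    t_stage: Optional[str] = None
    nodes_positive: Optional[bool] = None
    nodes_examined: Optional[int] = None
    genetic_syndrome: Optional[bool] = None
    synchronous_metastases: Optional[bool] = None
    recurrence: Optional[bool] = None
    rfs_months: Optional[float] = None
    recurrence_sites: frozenset = field(default_factory=frozenset)
    prs_months: Optional[float] = None
    prs_event: Optional[bool] = None
    os_months: Optional[float] = None
    os_event: Optional[bool] = None
    era: Optional[str] = None

    _ENUM_FIELDS = {
        "sex": SEXES,
        "asa": ASA_CLASSES,
        "location": LOCATIONS,
        "resection_type": RESECTION_TYPES,
        "grade": GRADES,
        "margin": MARGINS,
        "t_stage": T_STAGES,
        "era": ERAS,
    }

    def validate(self, row: Optional[int] = None) -> None:
        """Raise :class:`CohortValidationError` on any out-of-vocabulary value.

        ``row`` is included in the message when given (CSV provenance).
        """
        where = f" (row {row})" if row is not None else ""
        for name, allowed in self._ENUM_FIELDS.items():
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise CohortValidationError(
                    f"field {name!r}{where}: {value!r} not in {sorted(allowed)}"
                )
        for site in self.recurrence_sites:
            if site not in RECURRENCE_SITES:
                raise CohortValidationError(
                    f"field 'recurrence_sites'{where}: unknown site {site!r}"
                )
        for name in ("rfs_months", "prs_months", "os_months", "tumor_size"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise CohortValidationError(
                    f"field {name!r}{where}: negative value {value!r}"
                )


@dataclass
class ExclusionLog:
    """Per-patient exclusion reasons plus counts per reason.

    Every excluded patient appears exactly once, under the first failing
    criterion in :data:`EXCLUSION_REASONS` order.
    """

    reasons: dict = field(default_factory=dict)  # patient_id -> reason code

    def __len__(self) -> int:
        return len(self.reasons)

    @property
    def counts(self) -> dict:
        out = {reason: 0 for reason in EXCLUSION_REASONS}
        for reason in self.reasons.values():
            out[reason] += 1
        return out


@dataclass(frozen=True)
class ERStatus:
    """Early/late recurrence label relative to a months cut-off."""

    value: str  # "none" | "early" | "late"
    cutoff_months: float

    NONE = "none"
    EARLY = "early"
    LATE = "late"


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def _first_failing_reason(rec: PatientRecord) -> Optional[str]:
    if rec.grade == "G3":
        return "grade3"
    if rec.genetic_syndrome:
        return "genetic_syndrome"
    if rec.margin == "R2":
        return "r2_resection"
    if rec.synchronous_metastases:
        return "synchronous_metastases"
    if rec.recurrence is None:
        return "missing_recurrence_status"
    if rec.recurrence and rec.rfs_months is not None and rec.rfs_months < MIN_RFS_MONTHS:
        return "recurrence_lt_3mo"
    return None


def apply_eligibility_filters(
    records: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], ExclusionLog]:
    """Apply the study eligibility criteria.

    Excludes grade 3 tumors, known genetic syndromes, R2 resections,
    synchronous metastases at diagnosis, records with unknown recurrence
    status, and recurrences within 3 months of surgery.  Returns the eligible
    records (input order preserved) and an :class:`ExclusionLog`; the two
    partition the input exactly.
    """
    eligible: list[PatientRecord] = []
    log = ExclusionLog()
    for i, rec in enumerate(records):
        rec.validate(row=i)
        reason = _first_failing_reason(rec)
        if reason is None:
            eligible.append(rec)
        else:
            log.reasons[rec.patient_id] = reason
    return eligible, log


# ---------------------------------------------------------------------------
# Recurrence pattern and early/late classification
# ---------------------------------------------------------------------------

def classify_recurrence_pattern(sites: Iterable[str]) -> str:
    """Map a nonempty set of first-recurrence sites to one of three patterns.

    ``local`` if every site is in the remnant pancreas / cut surface /
    peri-pancreatic nodes; ``distant`` if none is; ``local_and_distant``
    otherwise.  Recurrence in organs other than pancreas, liver and regional
    nodes counts as distant.
    """
    sites = frozenset(sites)
    if not sites:
        raise ValueError("recurrence recorded without a site")
    unknown = sites - RECURRENCE_SITES
    if unknown:
        raise CohortValidationError(f"unknown recurrence sites: {sorted(unknown)}")
    has_local = bool(sites & LOCAL_SITES)
    has_distant = bool(sites & DISTANT_SITES)
    if has_local and has_distant:
        return LOCAL_AND_DISTANT
    return LOCAL if has_local else DISTANT


def classify_er_status(record: PatientRecord, cutoff_months: float) -> ERStatus:
    """Label a patient none/early/late relative to an RFS cut-off.

    A recurrence at exactly the cut-off counts as early (``<=`` convention,
    matching the 'within N months' reading of an early-recurrence window).
    """
    if cutoff_months <= MIN_RFS_MONTHS:
        raise ValueError(
            f"cutoff must exceed the {MIN_RFS_MONTHS}-month eligibility floor"
        )
    if not record.recurrence:
        return ERStatus(ERStatus.NONE, cutoff_months)
    if record.rfs_months is None:
        raise CohortValidationError(
            f"patient {record.patient_id}: recurrence without rfs_months"
        )
    if record.rfs_months <= cutoff_months:
        return ERStatus(ERStatus.EARLY, cutoff_months)
    return ERStatus(ERStatus.LATE, cutoff_months)


# ---------------------------------------------------------------------------
# CSV interface: header row with field names, booleans as 0/1, missing as
# empty string, recurrence_sites as a ';'-joined list.
# ---------------------------------------------------------------------------

_BOOL_FIELDS = (
    "functional", "symptomatic", "multifocal", "vascular_resection",
    "severe_complication", "lvi", "pni", "nodes_positive", "genetic_syndrome",
    "synchronous_metastases", "recurrence", "prs_event", "os_event",
)
_FLOAT_FIELDS = ("age", "bmi", "tumor_size", "rfs_months", "prs_months", "os_months")
_FIELD_NAMES = [f.name for f in dataclasses.fields(PatientRecord)]


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (booleans 0/1, sites ';'-joined)."""
    rows = []
    for rec in records:
        row = {}
        for name in _FIELD_NAMES:
            value = getattr(rec, name)
            if name == "recurrence_sites":
                row[name] = ";".join(sorted(value)) if value else ""
            elif name in _BOOL_FIELDS:
                row[name] = None if value is None else int(value)
            else:
                row[name] = value
        rows.append(row)
    return pd.DataFrame(rows, columns=_FIELD_NAMES)


def frame_to_records(frame: pd.DataFrame, validate: bool = True) -> list[PatientRecord]:
    """Inverse of :func:`records_to_frame`; validates vocabularies by default."""
    records = []
    for i, row in enumerate(frame.to_dict("records")):
        kwargs = {}
        for name in _FIELD_NAMES:
            raw = row.get(name)
            missing = raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == ""
            if name == "patient_id":
                kwargs[name] = str(raw)
            elif name == "recurrence_sites":
                kwargs[name] = (
                    frozenset() if missing else frozenset(str(raw).split(";"))
                )
            elif missing:
                kwargs[name] = None
            elif name in _BOOL_FIELDS:
                kwargs[name] = bool(int(raw))
            elif name in _FLOAT_FIELDS:
                kwargs[name] = float(raw)
            elif name == "nodes_examined":
                kwargs[name] = int(raw)
            else:
                kwargs[name] = str(raw)
        rec = PatientRecord(**kwargs)
        if validate:
            rec.validate(row=i)
        records.append(rec)
    return records


def write_cohort_csv(records: Iterable[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path, validate: bool = True) -> list[PatientRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=True)
    return frame_to_records(frame, validate=validate)
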