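"""Shared domain types for two-registry record linkage.

The linkage key is the quasi-identifier pair (date of birth, 4-digit postal
code prefix).  In the Dutch postal system the 4-digit prefix ("pc4")
identifies a neighbourhood of roughly 2,000 households, so the pair is
narrow but not unique: two women born on the same day in the same
neighbourhood share a key.  Everything downstream — pseudonymization,
deterministic linkage, disambiguation — operates on this key or on an
aggregated, privacy-reduced view of it (birth year/quarter + pc4).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Any

__all__ = [
    "RegistryId",
    "Sex",
    "CodeSystem",
    "DiagnosisCode",
    "SourceRecord",
    "LinkageKey",
    "AggregatedQID",
    "RecordValidationError",
    "POSTAL_CODE_RE",
    "BREAST_CANCER_ICD10_PREFIX",
    "BREAST_CANCER_ICPC_CODE",
    "extract_linkage_key",
    "aggregate_qid",
    "has_breast_cancer_dx",
]

#: Dutch postal code: 4 digits, optionally followed by a 2-letter suffix.
POSTAL_CODE_RE = re.compile(r"^\d{4}([A-Z]{2})?$")

#: ICD-10 topography family for malignant neoplasm of breast (cancer registry).
BREAST_CANCER_ICD10_PREFIX = "C50"
#: ICPC-1 code for malignant neoplasm of breast (GP registry).
BREAST_CANCER_ICPC_CODE = "X76"


class RegistryId(str, Enum):
    """Which of the two registries a record belongs to."""

    A_CANCER = "A_cancer"
    B_PRIMARY_CARE = "B_primary_care"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class CodeSystem(str, Enum):
    ICD10 = "ICD10"
    ICPC1 = "ICPC1"


class RecordValidationError(ValueError):
    """A record failed a format check; carries the offending record_id."""

    def __init__(self, record_id: str, reason: str):
        self.record_id = record_id
        self.reason = reason
        super().__init__(f"record {record_id!r}: {reason}")


@dataclass(frozen=True, slots=True)
class DiagnosisCode:
    """One coded diagnosis: coding system, code string and calendar year."""

    system: CodeSystem
    code: str
    year: int


@dataclass(slots=True)
class SourceRecord:
    """One person-row in a registry.

    ``attributes`` holds named clinical / stratification values (stage,
    surgery, practice id, registration date, ...).  They never participate
    in key extraction.
    """

    record_id: str
    registry_id: RegistryId
    sex: Sex
    date_of_birth: date
    postal_code: str
    diagnosis_codes: frozenset[DiagnosisCode] = frozenset()
    attributes: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True, slots=True)
class LinkageKey:
    """The exact deterministic match key: (date of birth, pc4)."""

    dob: date
    pc4: str


@dataclass(frozen=True, slots=True)
class AggregatedQID:
    """Privacy-reduced quasi-identifiers kept alongside the pseudonym:
    year and quarter of birth plus the 4-digit postal prefix."""

    birth_year: int
    birth_quarter: int
    pc4: str


def _validate_quasi_identifiers(record: SourceRecord) -> None:
    if not isinstance(record.date_of_birth, date):
        raise RecordValidationError(
            record.record_id, "date of birth missing or not a calendar date"
        )
    pc = record.postal_code
    if not isinstance(pc, str) or not POSTAL_CODE_RE.match(pc):
        raise RecordValidationError(
            record.record_id, f"malformed postal code {pc!r}"
        )


def extract_linkage_key(record: SourceRecord) -> LinkageKey:
    """Extract the (dob, pc4) linkage key, truncating a 6-character postal
    code to its 4-digit prefix.

    Raises
    ------
    RecordValidationError
        If the postal code is malformed or the date of birth missing.
    """
    _validate_quasi_identifiers(record)
    return LinkageKey(dob=record.date_of_birth, pc4=record.postal_code[:4])


def aggregate_qid(record: SourceRecord) -> AggregatedQID:
    """Aggregate quasi-identifiers to (birth year, birth quarter, pc4).

    The quarter is calendar-based: Q1 = Jan-Mar, ..., Q4 = Oct-Dec.
    """
    key = extract_linkage_key(record)
    return AggregatedQID(
        birth_year=key.dob.year,
        birth_quarter=(key.dob.month - 1) // 3 + 1,
        pc4=key.pc4,
    )


def has_breast_cancer_dx(record: SourceRecord | Any) -> bool:
    """True iff the record carries the registry's qualifying breast-cancer
    diagnosis: any ICD-10 code with prefix C50 in the cancer registry, the
    ICPC-1 code X76 in the primary-care registry.

    The code's year is deliberately not constrained: the two registries do
    not need to agree on a diagnosis date, only on the diagnosis itself.
    An empty code set yields False.  Works on any object exposing
    ``registry_id`` and ``diagnosis_codes``.
    """
    if record.registry_id == RegistryId.A_CANCER:
        return any(
            c.system == CodeSystem.ICD10
            and c.code.startswith(BREAST_CANCER_ICD10_PREFIX)
            for c in record.diagnosis_codes
        )
    return any(
        c.system == CodeSystem.ICPC1 and c.code == BREAST_CANCER_ICPC_CODE
        for c in record.diagnosis_codes
    )
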