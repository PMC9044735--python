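"""Three-party pseudonymization chain with key separation.

The flow mirrors how two registry holders link records through a trusted
third party (TTP) without either side revealing raw quasi-identifiers:

1. **Sender** — validates each record's formats, computes a *pre-pseudonym*
   (a keyed one-way transform of the linkage key under the sender secret),
   and aggregates the personal data to (birth year, birth quarter, pc4).
   The pre-pseudonym stream goes to the TTP; the aggregated data plus
   clinical payload go to the receiver.  Raw date of birth and full postal
   code leave the sender in neither stream.
2. **TTP** — re-keys pre-pseudonyms into *final pseudonyms* under its own
   secret.  Its interface accepts pseudonym strings only, so it can never
   see aggregated personal data.
3. **Receiver** — zips the final pseudonyms back with the aggregated data
   and clinical payload.  Records from the two registries that share a
   linkage key end up with the same final pseudonym, which is all the
   linkage engine needs.

The concrete transform is HMAC-SHA256 over the canonical serialization
``"YYYY-MM-DD|PPPP"`` (hex output).  Any keyed PRF satisfies the contracts;
this module simulates the data-flow separation, not production key
management.
"""

from __future__ import annotations

import hashlib
import hmac
from dataclasses import dataclass, field
from datetime import date
from typing import Any, Sequence

from .core_model import (
    AggregatedQID,
    DiagnosisCode,
    LinkageKey,
    RecordValidationError,
    RegistryId,
    Sex,
    SourceRecord,
    aggregate_qid,
    extract_linkage_key,
)

__all__ = [
    "ConfigurationError",
    "AlignmentError",
    "SenderRow",
    "SenderOutput",
    "PseudonymizedRecord",
    "pre_pseudonym",
    "sender_prepare",
    "ttp_transform",
    "receiver_combine",
]


class ConfigurationError(ValueError):
    """A secret is missing or empty."""


class AlignmentError(ValueError):
    """Pseudonym stream and payload stream have different lengths."""


def _require_secret(secret: bytes, who: str) -> None:
    if not isinstance(secret, (bytes, bytearray)) or len(secret) == 0:
        raise ConfigurationError(f"{who} secret must be a non-empty byte string")


def pre_pseudonym(key: LinkageKey, sender_secret: bytes) -> str:
    """Keyed one-way transform of a linkage key (HMAC-SHA256, hex)."""
    _require_secret(sender_secret, "sender")
    message = f"{key.dob.isoformat()}|{key.pc4}".encode("ascii")
    return hmac.new(bytes(sender_secret), message, hashlib.sha256).hexdigest()


@dataclass(slots=True)
class SenderRow:
    """One prepared row: pre-pseudonym plus the privacy-reduced payload.

    Contains no raw date of birth and no 6-character postal code.
    """

    pre_pseudonym: str
    registry_id: RegistryId
    record_id: str
    sex: Sex
    qid: AggregatedQID
    diagnosis_codes: frozenset[DiagnosisCode] = frozenset()
    attributes: dict[str, Any] = field(default_factory=dict)


@dataclass(slots=True)
class SenderOutput:
    rows: list[SenderRow]
    errors: list[tuple[str, str]]  # (record_id, reason) — reported, not dropped silently


@dataclass(slots=True)
class PseudonymizedRecord:
    """Receiver-side record: final pseudonym + aggregated QID + clinical
    payload.  The linkage key cannot be reconstructed beyond the
    (birth year, quarter, pc4) granularity."""

    pseudonym: str
    registry_id: RegistryId
    record_id: str
    sex: Sex
    qid: AggregatedQID
    diagnosis_codes: frozenset[DiagnosisCode] = frozenset()
    attributes: dict[str, Any] = field(default_factory=dict)


def _coerce_dob(record: SourceRecord) -> date:
    """Format check: the date of birth must be a calendar date or an
    ISO-8601 string.  Anything else (e.g. ``14/05/1957``) is rejected."""
    dob = record.date_of_birth
    if isinstance(dob, date):
        return dob
    if isinstance(dob, str):
        try:
            return date.fromisoformat(dob)
        except ValueError:
            pass
    raise RecordValidationError(
        record.record_id, f"date of birth {dob!r} not in the pre-specified format"
    )


def sender_prepare(
    records: Sequence[SourceRecord], sender_secret: bytes
) -> SenderOutput:
    """Sender stage: per-row format checks, pre-pseudonymization and
    quasi-identifier aggregation.

    Rows failing the checks are collected into ``errors`` with record id and
    reason; valid rows carry no field from which the raw linkage key could
    be recovered.
    """
    _require_secret(sender_secret, "sender")
    rows: list[SenderRow] = []
    errors: list[tuple[str, str]] = []
    for record in records:
        try:
            dob = _coerce_dob(record)
            checked = SourceRecord(
                record_id=record.record_id,
                registry_id=record.registry_id,
                sex=record.sex,
                date_of_birth=dob,
                postal_code=record.postal_code,
                diagnosis_codes=record.diagnosis_codes,
                attributes=record.attributes,
            )
            key = extract_linkage_key(checked)
            rows.append(
                SenderRow(
                    pre_pseudonym=pre_pseudonym(key, sender_secret),
                    registry_id=record.registry_id,
                    record_id=record.record_id,
                    sex=record.sex,
                    qid=aggregate_qid(checked),
                    diagnosis_codes=record.diagnosis_codes,
                    attributes=dict(record.attributes),
                )
            )
        except RecordValidationError as err:
            errors.append((err.record_id, err.reason))
    return SenderOutput(rows=rows, errors=errors)


def ttp_transform(pre_pseudonyms: Sequence[str], ttp_secret: bytes) -> list[str]:
    """TTP stage: re-key pre-pseudonyms into final pseudonyms.

    The signature admits pseudonym strings only — aggregated personal data
    cannot be passed to this party.  Order- and length-preserving.
    """
    _require_secret(ttp_secret, "TTP")
    out: list[str] = []
    for p in pre_pseudonyms:
        if not isinstance(p, str):
            raise TypeError(
                "ttp_transform accepts pre-pseudonym strings only, "
                f"got {type(p).__name__}"
            )
        out.append(
            hmac.new(bytes(ttp_secret), p.encode("ascii"), hashlib.sha256).hexdigest()
        )
    return out


def _combine_one(
    final_pseudonyms: Sequence[str], rows: Sequence[SenderRow], label: str
) -> list[PseudonymizedRecord]:
    if len(final_pseudonyms) != len(rows):
        raise AlignmentError(
            f"registry {label}: {len(final_pseudonyms)} final pseudonyms "
            f"vs {len(rows)} payload rows"
        )
    return [
        PseudonymizedRecord(
            pseudonym=fp,
            registry_id=row.registry_id,
            record_id=row.record_id,
            sex=row.sex,
            qid=row.qid,
            diagnosis_codes=row.diagnosis_codes,
            attributes=row.attributes,
        )
        for fp, row in zip(final_pseudonyms, rows)
    ]


def receiver_combine(
    final_pseudonyms_a: Sequence[str],
    rows_a: Sequence[SenderRow],
    final_pseudonyms_b: Sequence[str],
    rows_b: Sequence[SenderRow],
) -> tuple[list[PseudonymizedRecord], list[PseudonymizedRecord]]:
    """Receiver stage: align each registry's final-pseudonym stream with its
    payload stream (both row-ordered) into pseudonymized registries.

    Records of the two registries that shared a linkage key now share a
    final pseudonym, provided both passed through the same sender and TTP
    secrets.
    """
    return (
        _combine_one(final_pseudonyms_a, rows_a, "A"),
        _combine_one(final_pseudonyms_b, rows_b, "B"),
    )
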