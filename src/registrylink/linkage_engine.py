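"""Deterministic linkage of the cancer registry (A) against the
primary-care registry (B) on the (date of birth, pc4) key, with
diagnosis-based disambiguation.

The algorithm, applied to the female subsets of both registries:

1. A-records whose key is shared by another A-record are excluded —
   correct linkage cannot be ascertained for them.
2. Remaining A-records whose key does not occur in B are unmatched.
3. Key occurs once in B: the A-record is included iff that B-record
   carries the qualifying GP diagnosis (X76); otherwise it stays a
   matched-but-unconfirmed record.
4. Key occurs more than once in B: the A-record is included iff exactly
   one candidate carries the diagnosis (that candidate is the match);
   with zero or several diagnosis-bearing candidates the match is
   unresolvable.

Requiring the diagnosis in both registries trades sensitivity for
positive predictive value: it removes most false key-matches at the cost
of losing true patients whose GP never recorded the diagnosis.

The engine runs identically on raw :class:`~registrylink.core_model.SourceRecord`
lists (keys computed directly) and on pseudonymized registries (the final
pseudonym *is* the key), so pseudonymization commutes with linkage.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Hashable, Sequence

from .core_model import Sex, extract_linkage_key, has_breast_cancer_dx
from .pseudonymization import PseudonymizedRecord

__all__ = [
    "Disposition",
    "LinkageResult",
    "FlowReport",
    "record_key",
    "partition_by_key_uniqueness",
    "link_registries",
    "brute_force_link",
    "flow_report",
]


class Disposition(str, Enum):
    """Per-A-record outcome of the linkage flow."""

    EXCLUDED_NONUNIQUE_IN_A = "excluded_nonunique_in_A"
    UNMATCHED = "unmatched"
    MATCHED_UNIQUE_NO_DX = "matched_unique_no_dx"
    INCLUDED_UNIQUE_WITH_DX = "included_unique_with_dx"
    MATCHED_NONUNIQUE_AMBIGUOUS_OR_NO_DX = "matched_nonunique_ambiguous_or_no_dx"
    INCLUDED_NONUNIQUE_RESOLVED = "included_nonunique_resolved"


INCLUDED_DISPOSITIONS = frozenset(
    {Disposition.INCLUDED_UNIQUE_WITH_DX, Disposition.INCLUDED_NONUNIQUE_RESOLVED}
)


def record_key(record: Any) -> Hashable:
    """Linkage key of a record: the final pseudonym for pseudonymized
    records, the raw (dob, pc4) key otherwise."""
    if isinstance(record, PseudonymizedRecord):
        return record.pseudonym
    return extract_linkage_key(record)


@dataclass(slots=True)
class LinkageResult:
    """Dispositions partition the female A-cohort; ``matched_pairs`` holds
    one (A record_id, B record_id) pair per included A-record.

    ``audit`` carries side counters (non-female removals, the split of
    unresolvable non-unique matches into zero-diagnosis vs ambiguous).
    ``b_candidate_counts`` maps each key-matched A record_id to the number
    of B-records sharing its key.
    """

    dispositions: dict[str, Disposition] = field(default_factory=dict)
    matched_pairs: list[tuple[str, str]] = field(default_factory=list)
    audit: dict[str, int] = field(default_factory=dict)
    b_candidate_counts: dict[str, int] = field(default_factory=dict)

    @property
    def included_ids(self) -> set[str]:
        return {
            rid
            for rid, d in self.dispositions.items()
            if d in INCLUDED_DISPOSITIONS
        }


def partition_by_key_uniqueness(
    registry: Sequence[Any],
) -> tuple[list[Any], dict[Hashable, list[Any]]]:
    """Split a registry into records with a unique key and groups of
    records sharing a key (returned with the shared key)."""
    by_key: dict[Hashable, list[Any]] = defaultdict(list)
    for r in registry:
        by_key[record_key(r)].append(r)
    unique = [rs[0] for rs in by_key.values() if len(rs) == 1]
    groups = {k: rs for k, rs in by_key.items() if len(rs) > 1}
    return unique, groups


def _check_namespaces(a: Sequence[Any], b: Sequence[Any]) -> None:
    ids_a = {r.record_id for r in a}
    ids_b = {r.record_id for r in b}
    shared = ids_a & ids_b
    if shared:
        raise ValueError(
            f"record_id namespaces of A and B overlap: {sorted(shared)[:5]}"
        )


def _female(records: Sequence[Any]) -> tuple[list[Any], int, int]:
    kept, n_male, n_unknown = [], 0, 0
    for r in records:
        if r.sex == Sex.FEMALE:
            kept.append(r)
        elif r.sex == Sex.MALE:
            n_male += 1
        else:
            n_unknown += 1
    return kept, n_male, n_unknown


def link_registries(a: Sequence[Any], b: Sequence[Any]) -> LinkageResult:
    """Run the deterministic linkage flow of registry A against registry B.

    Both inputs are restricted to females here (removals audited).  A and B
    must use disjoint record_id namespaces.
    """
    _check_namespaces(a, b)
    fem_a, male_a, unk_a = _female(a)
    fem_b, male_b, unk_b = _female(b)

    result = LinkageResult(
        audit={
            "removed_male_a": male_a,
            "removed_unknown_sex_a": unk_a,
            "removed_male_b": male_b,
            "removed_unknown_sex_b": unk_b,
            "nonunique_b_zero_dx": 0,
            "nonunique_b_ambiguous_dx": 0,
        }
    )

    unique_a, groups_a = partition_by_key_uniqueness(fem_a)
    for group in groups_a.values():
        for r in group:
            result.dispositions[r.record_id] = Disposition.EXCLUDED_NONUNIQUE_IN_A

    b_by_key: dict[Hashable, list[Any]] = defaultdict(list)
    for r in fem_b:
        b_by_key[record_key(r)].append(r)

    for r in unique_a:
        candidates = b_by_key.get(record_key(r))
        if not candidates:
            result.dispositions[r.record_id] = Disposition.UNMATCHED
            continue
        result.b_candidate_counts[r.record_id] = len(candidates)
        if len(candidates) == 1:
            if has_breast_cancer_dx(candidates[0]):
                result.dispositions[r.record_id] = Disposition.INCLUDED_UNIQUE_WITH_DX
                result.matched_pairs.append((r.record_id, candidates[0].record_id))
            else:
                result.dispositions[r.record_id] = Disposition.MATCHED_UNIQUE_NO_DX
        else:
            with_dx = [c for c in candidates if has_breast_cancer_dx(c)]
            if len(with_dx) == 1:
                result.dispositions[r.record_id] = (
                    Disposition.INCLUDED_NONUNIQUE_RESOLVED
                )
                result.matched_pairs.append((r.record_id, with_dx[0].record_id))
            else:
                result.dispositions[r.record_id] = (
                    Disposition.MATCHED_NONUNIQUE_AMBIGUOUS_OR_NO_DX
                )
                bucket = (
                    "nonunique_b_zero_dx" if not with_dx else "nonunique_b_ambiguous_dx"
                )
                result.audit[bucket] += 1

    # Two A-records cannot both survive step 1 with the same key, so no
    # B-record can be claimed twice; assert rather than assume.
    b_sides = [p[1] for p in result.matched_pairs]
    assert len(b_sides) == len(set(b_sides)), "a B-record was matched twice"
    return result


def brute_force_link(
    a: Sequence[Any], b: Sequence[Any], max_pairs: int = 1_000_000
) -> LinkageResult:
    """Naive all-pairs reference implementation of :func:`link_registries`
    (test oracle only).  Refuses instances above ``max_pairs`` comparisons.
    """
    if len(a) * len(b) > max_pairs:
        raise ValueError(
            f"brute_force_link refuses {len(a)}x{len(b)} (> {max_pairs} pairs)"
        )
    _check_namespaces(a, b)
    fem_a, male_a, unk_a = _female(a)
    fem_b, male_b, unk_b = _female(b)
    result = LinkageResult(
        audit={
            "removed_male_a": male_a,
            "removed_unknown_sex_a": unk_a,
            "removed_male_b": male_b,
            "removed_unknown_sex_b": unk_b,
            "nonunique_b_zero_dx": 0,
            "nonunique_b_ambiguous_dx": 0,
        }
    )
    for r in fem_a:
        key = record_key(r)
        # scan A for a same-key sibling
        if sum(1 for other in fem_a if record_key(other) == key) > 1:
            result.dispositions[r.record_id] = Disposition.EXCLUDED_NONUNIQUE_IN_A
            continue
        candidates = [s for s in fem_b if record_key(s) == key]
        if not candidates:
            result.dispositions[r.record_id] = Disposition.UNMATCHED
            continue
        result.b_candidate_counts[r.record_id] = len(candidates)
        with_dx = [c for c in candidates if has_breast_cancer_dx(c)]
        if len(candidates) == 1:
            if with_dx:
                result.dispositions[r.record_id] = Disposition.INCLUDED_UNIQUE_WITH_DX
                result.matched_pairs.append((r.record_id, candidates[0].record_id))
            else:
                result.dispositions[r.record_id] = Disposition.MATCHED_UNIQUE_NO_DX
        elif len(with_dx) == 1:
            result.dispositions[r.record_id] = Disposition.INCLUDED_NONUNIQUE_RESOLVED
            result.matched_pairs.append((r.record_id, with_dx[0].record_id))
        else:
            result.dispositions[r.record_id] = (
                Disposition.MATCHED_NONUNIQUE_AMBIGUOUS_OR_NO_DX
            )
            bucket = "nonunique_b_zero_dx" if not with_dx else "nonunique_b_ambiguous_dx"
            result.audit[bucket] += 1
    return result


@dataclass(slots=True)
class FlowReport:
    """Counts at every node of the linkage flow, with percentage helpers.

    Percentages are reported against two labelled denominators: the total
    female A-cohort and the stage-specific denominator of each branch.
    """

    total_a: int
    excluded_nonunique_a: int
    remaining: int
    unmatched: int
    matched_in_b: int
    unique_in_b: int
    unique_with_dx: int
    unique_no_dx: int
    nonunique_in_b: int
    nonunique_resolved: int
    nonunique_unresolved: int
    included: int

    def validate(self) -> None:
        checks = {
            "remaining = total_a - excluded_nonunique_a":
                self.remaining == self.total_a - self.excluded_nonunique_a,
            "remaining = unmatched + matched_in_b":
                self.remaining == self.unmatched + self.matched_in_b,
            "matched_in_b = unique_in_b + nonunique_in_b":
                self.matched_in_b == self.unique_in_b + self.nonunique_in_b,
            "unique_in_b = unique_with_dx + unique_no_dx":
                self.unique_in_b == self.unique_with_dx + self.unique_no_dx,
            "nonunique_in_b = nonunique_resolved + nonunique_unresolved":
                self.nonunique_in_b
                == self.nonunique_resolved + self.nonunique_unresolved,
            "included = unique_with_dx + nonunique_resolved":
                self.included == self.unique_with_dx + self.nonunique_resolved,
            "all counts >= 0": all(
                getattr(self, f) >= 0 for f in self.__dataclass_fields__
            ),
        }
        failed = [name for name, ok in checks.items() if not ok]
        if failed:
            raise ValueError("flow identities violated: " + "; ".join(failed))

    @staticmethod
    def _pct(num: int, den: int, ndigits: int = 1):
        """Percentage to one decimal; ``None`` (flagged) on a zero
        denominator rather than a propagated NaN."""
        if den == 0:
            return None
        return round(100.0 * num / den, ndigits)

    def percentages(self) -> dict[str, dict]:
        """Labelled percentages with explicit numerators/denominators."""
        entries = {
            "excluded_of_total": (self.excluded_nonunique_a, self.total_a),
            "matched_of_remaining": (self.matched_in_b, self.remaining),
            "matched_of_total": (self.matched_in_b, self.total_a),
            "unique_with_dx_of_unique": (self.unique_with_dx, self.unique_in_b),
            "included_of_total": (self.included, self.total_a),
        }
        return {
            name: {
                "numerator": num,
                "denominator": den,
                "percent": self._pct(num, den),
                "undefined": den == 0,
            }
            for name, (num, den) in entries.items()
        }

    def to_dict(self) -> dict:
        counts = {f: getattr(self, f) for f in self.__dataclass_fields__}
        return {"counts": counts, "percentages": self.percentages()}

    def to_text(self) -> str:
        """Aligned text table in flow order."""
        p = self.percentages()

        def pct(name):
            v = p[name]["percent"]
            return "   n/a" if v is None else f"{v:6.1f}%"

        lines = [
            f"{'A-cohort (female)':<42}{self.total_a:>10}",
            f"{'  excluded: key non-unique within A':<42}{self.excluded_nonunique_a:>10}  {pct('excluded_of_total')} of total",
            f"{'  remaining':<42}{self.remaining:>10}",
            f"{'    key not present in B (unmatched)':<42}{self.unmatched:>10}",
            f"{'    key present in B (matched)':<42}{self.matched_in_b:>10}  {pct('matched_of_remaining')} of remaining",
            f"{'      key unique in B':<42}{self.unique_in_b:>10}",
            f"{'        with GP diagnosis -> included':<42}{self.unique_with_dx:>10}  {pct('unique_with_dx_of_unique')} of unique",
            f"{'        without GP diagnosis':<42}{self.unique_no_dx:>10}",
            f"{'      key non-unique in B':<42}{self.nonunique_in_b:>10}",
            f"{'        exactly one with dx -> included':<42}{self.nonunique_resolved:>10}",
            f"{'        zero or several with dx':<42}{self.nonunique_unresolved:>10}",
            f"{'  final included':<42}{self.included:>10}  {pct('included_of_total')} of total",
        ]
        return "\n".join(lines)


def flow_report(result: LinkageResult, denominator_total: int | None = None) -> FlowReport:
    """Aggregate a :class:`LinkageResult` into node counts.

    ``denominator_total`` overrides the total-cohort denominator (e.g. when
    the published cohort count differs slightly from the records on hand);
    by default it is the number of disposed A-records.
    """
    c = Counter(result.dispositions.values())
    excluded = c[Disposition.EXCLUDED_NONUNIQUE_IN_A]
    unmatched = c[Disposition.UNMATCHED]
    unique_with_dx = c[Disposition.INCLUDED_UNIQUE_WITH_DX]
    unique_no_dx = c[Disposition.MATCHED_UNIQUE_NO_DX]
    nonunique_resolved = c[Disposition.INCLUDED_NONUNIQUE_RESOLVED]
    nonunique_unresolved = c[Disposition.MATCHED_NONUNIQUE_AMBIGUOUS_OR_NO_DX]
    total = len(result.dispositions)
    report = FlowReport(
        total_a=denominator_total if denominator_total is not None else total,
        excluded_nonunique_a=excluded,
        remaining=total - excluded,
        unmatched=unmatched,
        matched_in_b=total - excluded - unmatched,
        unique_in_b=unique_with_dx + unique_no_dx,
        unique_with_dx=unique_with_dx,
        unique_no_dx=unique_no_dx,
        nonunique_in_b=nonunique_resolved + nonunique_unresolved,
        nonunique_resolved=nonunique_resolved,
        nonunique_unresolved=nonunique_unresolved,
        included=unique_with_dx + nonunique_resolved,
    )
    if denominator_total is None:
        report.validate()
    return report
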