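"""Inclusion-bias tables and the GP validation-sample builder.

Linkage that conditions on residence and on GP diagnosis recording does not
miss patients at random: women who moved after diagnosis, or whose GP never
coded the diagnosis, are under-represented.  The inclusion table quantifies
this by comparing, per characteristic (year of diagnosis, age band, stage,
treatment, ...), the linked fraction across categories, with a Pearson
chi-square test of independence between category and inclusion status.

The validation sampler reproduces the audit procedure in which GP practices
with relatively many linked patients are asked to confirm the diagnosis for
their patients, using only privacy-reduced fields (year/quarter of birth,
registration date, diagnosis years, last visit) — never a raw date of birth
or postal code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
from scipy import stats

from .core_model import (
    BREAST_CANCER_ICD10_PREFIX,
    BREAST_CANCER_ICPC_CODE,
    CodeSystem,
)

__all__ = [
    "DegenerateTableError",
    "CategoryRow",
    "CharacteristicBlock",
    "InclusionTable",
    "ValidationSheet",
    "chi_square_independence",
    "inclusion_table",
    "gp_validation_sample",
]


class DegenerateTableError(ValueError):
    """A contingency table has a zero row or column margin."""


def chi_square_independence(table: Any) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a counts matrix.

    Returns ``(statistic, df, p_value)`` with statistic Σ(O−E)²/E,
    df = (r−1)(c−1) and an upper-tail chi-square p-value.  No continuity
    correction is applied.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a counts matrix with at least 2 rows and 2 columns")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise DegenerateTableError("a row or column margin sums to zero")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


@dataclass(slots=True)
class CategoryRow:
    category: str
    n_total: int
    n_included: int
    pct_included: float | None  # None when n_total == 0


@dataclass(slots=True)
class CharacteristicBlock:
    name: str
    rows: list[CategoryRow]
    statistic: float | None
    df: int | None
    p_value: float | None
    notes: list[str] = field(default_factory=list)


@dataclass(slots=True)
class InclusionTable:
    cohort_n: int
    included_n: int
    blocks: list[CharacteristicBlock]

    def block(self, name: str) -> CharacteristicBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


def inclusion_table(
    cohort: Sequence[Any],
    included_ids: Iterable[str],
    characteristics: Sequence[str],
) -> InclusionTable:
    """Per-characteristic inclusion counts, percentages and homogeneity test.

    ``cohort`` is the full female A-cohort (records exposing ``record_id``
    and ``attributes``); ``included_ids`` the record ids that made it into
    the linked registry.  A record with a missing attribute value falls in
    an explicit ``Unknown`` category.  Categories with zero N are flagged
    and left out of the test; no multiple-testing adjustment is applied
    across characteristics.
    """
    included = set(included_ids)
    blocks: list[CharacteristicBlock] = []
    for char in characteristics:
        totals: dict[str, int] = {}
        incl: dict[str, int] = {}
        for r in cohort:
            cat = str(r.attributes.get(char, "Unknown"))
            totals[cat] = totals.get(cat, 0) + 1
            if r.record_id in included:
                incl[cat] = incl.get(cat, 0) + 1
        rows = [
            CategoryRow(
                category=cat,
                n_total=n,
                n_included=incl.get(cat, 0),
                pct_included=None if n == 0 else round(100.0 * incl.get(cat, 0) / n, 1),
            )
            for cat, n in sorted(totals.items())
        ]
        notes: list[str] = []
        testable = [r for r in rows if r.n_total > 0]
        if len(testable) < len(rows):
            notes.append("zero-N categories excluded from the test")
        stat = df = p = None
        if len(testable) >= 2 and len(cohort) > 0:
            table = [[r.n_included, r.n_total - r.n_included] for r in testable]
            try:
                stat, df, p = chi_square_independence(table)
            except DegenerateTableError:
                notes.append("degenerate table (zero margin); test not computed")
        elif len(cohort) == 0:
            notes.append("empty cohort; no test")
        blocks.append(
            CharacteristicBlock(
                name=char, rows=rows, statistic=stat, df=df, p_value=p, notes=notes
            )
        )
    return InclusionTable(
        cohort_n=len(cohort), included_n=len(included), blocks=blocks
    )


@dataclass(slots=True)
class ValidationSheet:
    """One patient row sent to a GP practice for diagnosis confirmation.

    Deliberately excludes the raw date of birth and any postal code: the
    practice can locate the patient from year/quarter of birth, the
    registration date and the diagnosis/visit history alone.
    """

    practice_id: str
    b_record_id: str
    birth_year: int
    birth_quarter: int
    registration_date: str | None
    dx_year_cancer_registry: int | None
    dx_year_gp_registry: int | None
    last_visit_date: str | None
    last_visit_codes: str | None
    status: str = "pending"  # confirmed | not_confirmed | pending


def _dx_year(codes, system: CodeSystem, match) -> int | None:
    years = [c.year for c in codes if c.system == system and match(c.code)]
    return min(years) if years else None


def gp_validation_sample(
    linked_pairs: Sequence[tuple[Any, Any]],
    target_n: int = 44,
    seed: int | None = None,
) -> list[ValidationSheet]:
    """Draw the practice-based validation sample.

    Practices are ranked by their number of linked patients; practices are
    then drawn at random with probability proportional to size from the top
    half of that ranking, and *all* linked patients of a drawn practice are
    added, until the cumulative patient count reaches ``target_n`` (default
    44).  If the top half is exhausted first, sampling extends to the
    remaining practices; if the whole cohort is smaller than ``target_n``,
    all patients are returned with a shortfall warning.

    ``linked_pairs`` are (A-record, B-record) matched pairs; the B-record's
    attributes supply practice_id, registration date and last-visit fields.
    """
    if target_n < 0:
        raise ValueError("target_n must be >= 0")
    if target_n == 0:
        return []
    rng = np.random.default_rng(seed)

    by_practice: dict[str, list[tuple[Any, Any]]] = {}
    for a_rec, b_rec in linked_pairs:
        pid = str(b_rec.attributes.get("practice_id", "unknown"))
        by_practice.setdefault(pid, []).append((a_rec, b_rec))

    ranked = sorted(by_practice.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n_top = max(1, (len(ranked) + 1) // 2) if ranked else 0
    pools = [ranked[:n_top], ranked[n_top:]]

    chosen: list[tuple[str, list[tuple[Any, Any]]]] = []
    total = 0
    for pool in pools:
        pool = list(pool)
        while pool and total < target_n:
            sizes = np.array([len(ps) for _, ps in pool], dtype=float)
            idx = int(rng.choice(len(pool), p=sizes / sizes.sum()))
            pid, patients = pool.pop(idx)
            chosen.append((pid, patients))
            total += len(patients)
        if total >= target_n:
            break
    if total < target_n:
        warnings.warn(
            f"validation cohort has only {total} linked patients "
            f"(target {target_n}); returning all",
            stacklevel=2,
        )

    sheets: list[ValidationSheet] = []
    for pid, patients in chosen:
        for a_rec, b_rec in patients:
            qid = getattr(b_rec, "qid", None)
            if qid is not None:
                birth_year, birth_quarter = qid.birth_year, qid.birth_quarter
            else:
                dob = b_rec.date_of_birth
                birth_year, birth_quarter = dob.year, (dob.month - 1) // 3 + 1
            sheets.append(
                ValidationSheet(
                    practice_id=pid,
                    b_record_id=b_rec.record_id,
                    birth_year=birth_year,
                    birth_quarter=birth_quarter,
                    registration_date=b_rec.attributes.get("registration_date"),
                    dx_year_cancer_registry=_dx_year(
                        a_rec.diagnosis_codes,
                        CodeSystem.ICD10,
                        lambda c: c.startswith(BREAST_CANCER_ICD10_PREFIX),
                    ),
                    dx_year_gp_registry=_dx_year(
                        b_rec.diagnosis_codes,
                        CodeSystem.ICPC1,
                        lambda c: c == BREAST_CANCER_ICPC_CODE,
                    ),
                    last_visit_date=b_rec.attributes.get("last_encounter_date"),
                    last_visit_codes=b_rec.attributes.get("last_encounter_codes"),
                )
            )
    return sheets
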