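"""Collision analytics, linkage performance against ground truth, and
case-control dilution.

The (date of birth, pc4) key is narrow but not unique; with ``N`` records
spread over ``C`` key cells, the probability that a given record shares its
cell with at least one other is ``1 - (1 - 1/C)^(N-1)`` under uniform
occupancy.  Collisions drive both the within-registry exclusions and the
false-match risk of deterministic linkage.

Ground-truth comparison yields pair-level sensitivity (true linkable pairs
recovered) and PPV (reported pairs joining the same person).  Finally,
true cases that stay unlinked — e.g. movers — may later be drawn as
*controls* in case-control studies built on the linked registry; the
dilution model quantifies how that contamination attenuates an odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import numpy as np

from .linkage_engine import LinkageResult
from .synthetic_registry import GroundTruth

__all__ = [
    "CollisionRate",
    "PerformanceMetrics",
    "DilutionResult",
    "expected_collision_rate",
    "linkage_performance",
    "subgroup_inclusion",
    "control_contamination",
    "dilution_analysis",
]


@dataclass(slots=True)
class CollisionRate:
    per_record_probability: float
    expected_colliding_records: float


def expected_collision_rate(
    n_records: int,
    n_cells: int | None = None,
    cell_probs: Sequence[float] | None = None,
) -> CollisionRate:
    """Expected fraction (and count) of records sharing a key cell.

    With uniform occupancy over ``n_cells`` the per-record collision
    probability is ``1 - (1 - 1/C)^(N-1)``.  A ``cell_probs`` vector gives
    the non-uniform generalization: a record in cell *j* (probability
    ``q_j``) collides with probability ``1 - (1 - q_j)^(N-1)``, averaged
    over the cell distribution.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if (n_cells is None) == (cell_probs is None):
        raise ValueError("give exactly one of n_cells or cell_probs")
    if cell_probs is not None:
        q = np.asarray(cell_probs, dtype=float)
        if (q < 0).any() or not np.isclose(q.sum(), 1.0):
            raise ValueError("cell_probs must be a probability vector")
        p = float(np.sum(q * (1.0 - (1.0 - q) ** (n_records - 1))))
    else:
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        p = 1.0 - (1.0 - 1.0 / n_cells) ** (n_records - 1)
    return CollisionRate(
        per_record_probability=p, expected_colliding_records=n_records * p
    )


@dataclass(slots=True)
class PerformanceMetrics:
    """Pair-level linkage quality against ground truth (rates in [0, 1];
    None when the denominator is empty)."""

    sensitivity: float | None
    ppv: float | None
    n_true_linkable_pairs: int
    n_reported_pairs: int
    n_correct_pairs: int
    false_match_count: int


def linkage_performance(
    result: LinkageResult, truth: GroundTruth
) -> PerformanceMetrics:
    """Score a linkage result against ground truth.

    A reported pair is correct iff both records belong to the same person.
    The sensitivity denominator counts persons truly present in both
    registries with identical linkage keys (a person whose key changed —
    a mover — is not linkable by this design and does not count against
    sensitivity).
    """
    unknown = [
        rid
        for pair in result.matched_pairs
        for rid in pair
        if rid not in truth.by_record
    ]
    if unknown:
        raise ValueError(f"records absent from ground truth: {sorted(unknown)[:5]}")

    n_true = sum(1 for t in truth.persons.values() if t.keys_equal)
    correct = sum(
        1
        for a_id, b_id in result.matched_pairs
        if truth.person_of(a_id) == truth.person_of(b_id)
    )
    n_rep = len(result.matched_pairs)
    return PerformanceMetrics(
        sensitivity=None if n_true == 0 else correct / n_true,
        ppv=None if n_rep == 0 else correct / n_rep,
        n_true_linkable_pairs=n_true,
        n_reported_pairs=n_rep,
        n_correct_pairs=correct,
        false_match_count=n_rep - correct,
    )


def subgroup_inclusion(
    cohort: Sequence[Any], included_ids: Iterable[str], attribute: str
) -> dict[str, float]:
    """Inclusion probability per category of an attribute (empty category
    maps are simply absent)."""
    included = set(included_ids)
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for r in cohort:
        cat = str(r.attributes.get(attribute, "Unknown"))
        totals[cat] = totals.get(cat, 0) + 1
        if r.record_id in included:
            hits[cat] = hits.get(cat, 0) + 1
    return {cat: hits.get(cat, 0) / n for cat, n in totals.items()}


def control_contamination(truth: GroundTruth, result: LinkageResult) -> float:
    """Fraction of the candidate-control pool (persons in registry B not
    linked as cases) who are in truth cases — the contamination rate ``f``
    feeding :func:`dilution_analysis`."""
    included_persons = {truth.person_of(a_id) for a_id, _ in result.matched_pairs}
    pool = [
        t
        for t in truth.persons.values()
        if t.b_record_id is not None and t.person_id not in included_persons
    ]
    if not pool:
        raise ValueError("empty control pool")
    return sum(1 for t in pool if t.true_dx) / len(pool)


@dataclass(slots=True)
class DilutionResult:
    observed_odds_ratio: float
    true_odds_ratio: float
    contamination_fraction: float
    case_exposure_prevalence: float
    contaminated_control_prevalence: float


def dilution_analysis(
    true_odds_ratio: float,
    control_exposure_prevalence: float,
    contamination_fraction: float,
) -> DilutionResult:
    """Attenuated odds ratio when a fraction ``f`` of controls are in truth
    cases.

    Contaminated controls are modelled as a mixture: with probability ``f``
    a control's exposure is drawn from the case exposure distribution.  The
    case exposure prevalence follows from the true odds ratio and the clean
    control prevalence; the observed odds ratio compares cases against the
    mixed control pool.  Attenuation is monotone in ``f`` and the null
    (odds ratio 1) is preserved for every ``f``.
    """
    if not 0.0 < control_exposure_prevalence < 1.0:
        raise ValueError("control exposure prevalence must be strictly inside (0, 1)")
    if not 0.0 <= contamination_fraction <= 1.0:
        raise ValueError("contamination fraction must be in [0, 1]")
    if true_odds_ratio <= 0.0:
        raise ValueError("odds ratio must be positive")
    p0 = control_exposure_prevalence
    case_odds = true_odds_ratio * p0 / (1.0 - p0)
    p1 = case_odds / (1.0 + case_odds)
    p0_mixed = (1.0 - contamination_fraction) * p0 + contamination_fraction * p1
    observed = (p1 / (1.0 - p1)) / (p0_mixed / (1.0 - p0_mixed))
    return DilutionResult(
        observed_odds_ratio=observed,
        true_odds_ratio=true_odds_ratio,
        contamination_fraction=contamination_fraction,
        case_exposure_prevalence=p1,
        contaminated_control_prevalence=p0_mixed,
    )
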