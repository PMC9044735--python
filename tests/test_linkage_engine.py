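"""Deterministic linkage flow: worked instances, oracle equivalence,
flow-report arithmetic and commutation with pseudonymization."""

from datetime import date

import numpy as np
import pytest

from registrylink import (
    Disposition,
    Sex,
    brute_force_link,
    flow_report,
    link_registries,
    partition_by_key_uniqueness,
    receiver_combine,
    sender_prepare,
    ttp_transform,
)
from registrylink.linkage_engine import FlowReport
from .conftest import key_of, make_a, make_b, random_instance


def K(i):
    return key_of(i)


def test_partition_by_key_uniqueness_counts_groups():
    records = [make_a("a1", *K(1)), make_a("a2", *K(2)), make_a("a3", *K(2)),
               make_a("a4", *K(3))]
    unique, groups = partition_by_key_uniqueness(records)
    assert {r.record_id for r in unique} == {"a1", "a4"}
    assert [sorted(r.record_id for r in g) for g in groups.values()] == [["a2", "a3"]]

    unique, groups = partition_by_key_uniqueness([make_a(f"a{i}", *K(i)) for i in range(5)])
    assert len(unique) == 5 and not groups

    unique, groups = partition_by_key_uniqueness([make_a(f"a{i}", *K(0)) for i in range(6)])
    assert not unique and len(next(iter(groups.values()))) == 6


def test_worked_five_by_four_instance():
    """A 5x4 instance exercising every branch, checked against the naive
    all-pairs oracle."""
    a = [make_a("a1", *K(1)), make_a("a2", *K(2)), make_a("a3", *K(2)),
         make_a("a4", *K(3)), make_a("a5", *K(4))]
    b = [make_b("b1", *K(1), dx=True), make_b("b2", *K(3), dx=False),
         make_b("b3", *K(4), dx=True), make_b("b4", *K(4), dx=False)]
    result = link_registries(a, b)
    assert sorted(result.matched_pairs) == [("a1", "b1"), ("a5", "b3")]
    assert result.dispositions == {
        "a1": Disposition.INCLUDED_UNIQUE_WITH_DX,
        "a2": Disposition.EXCLUDED_NONUNIQUE_IN_A,
        "a3": Disposition.EXCLUDED_NONUNIQUE_IN_A,
        "a4": Disposition.MATCHED_UNIQUE_NO_DX,
        "a5": Disposition.INCLUDED_NONUNIQUE_RESOLVED,
    }
    oracle = brute_force_link(a, b)
    assert oracle.dispositions == result.dispositions
    assert sorted(oracle.matched_pairs) == sorted(result.matched_pairs)


def test_empty_b_leaves_every_unique_a_record_unmatched():
    a = [make_a("a1", *K(1)), make_a("a2", *K(2)), make_a("a3", *K(2))]
    result = link_registries(a, [])
    assert result.dispositions["a1"] == Disposition.UNMATCHED
    assert result.dispositions["a2"] == Disposition.EXCLUDED_NONUNIQUE_IN_A


def test_two_diagnosis_bearing_candidates_block_inclusion():
    a = [make_a("a1", *K(7))]
    b = [make_b("b1", *K(7), dx=True), make_b("b2", *K(7), dx=True)]
    result = link_registries(a, b)
    assert result.dispositions["a1"] == Disposition.MATCHED_NONUNIQUE_AMBIGUOUS_OR_NO_DX
    assert result.audit["nonunique_b_ambiguous_dx"] == 1
    assert not result.matched_pairs


def test_zero_diagnosis_candidates_audited_separately_from_ambiguous():
    a = [make_a("a1", *K(7)), make_a("a2", *K(8))]
    b = [make_b("b1", *K(7), dx=False), make_b("b2", *K(7), dx=False),
         make_b("b3", *K(8), dx=True), make_b("b4", *K(8), dx=True)]
    result = link_registries(a, b)
    assert result.audit["nonunique_b_zero_dx"] == 1
    assert result.audit["nonunique_b_ambiguous_dx"] == 1


def test_non_female_records_are_removed_and_audited():
    a = [make_a("a1", *K(1)), make_a("a2", *K(2), sex=Sex.MALE),
         make_a("a3", *K(3), sex=Sex.UNKNOWN)]
    b = [make_b("b1", *K(1), dx=True), make_b("b2", *K(1), sex=Sex.MALE)]
    result = link_registries(a, b)
    assert set(result.dispositions) == {"a1"}
    assert result.dispositions["a1"] == Disposition.INCLUDED_UNIQUE_WITH_DX
    assert result.audit["removed_male_a"] == 1
    assert result.audit["removed_unknown_sex_a"] == 1
    assert result.audit["removed_male_b"] == 1


def test_shared_record_id_namespaces_are_rejected():
    with pytest.raises(ValueError, match="namespaces"):
        link_registries([make_a("x", *K(1))], [make_b("x", *K(2))])


def test_oracle_equivalence_on_randomized_instances(rng):
    """link_registries and the all-pairs oracle agree on 250 random small
    instances over a tight keyspace."""
    for _ in range(250):
        a, b = random_instance(rng)
        fast, slow = link_registries(a, b), brute_force_link(a, b)
        assert fast.dispositions == slow.dispositions
        assert sorted(fast.matched_pairs) == sorted(slow.matched_pairs)
        assert fast.audit == slow.audit
        flow_report(fast).validate()


def test_brute_force_refuses_oversized_instances():
    a = [make_a(f"a{i}", *K(i)) for i in range(40)]
    b = [make_b(f"b{i}", *K(i)) for i in range(30)]
    with pytest.raises(ValueError, match="refuses"):
        brute_force_link(a, b, max_pairs=1000)


def test_removing_a_b_record_only_adds_inclusions_via_disambiguation(rng):
    """Characterization: deleting B-record r newly includes A-record a iff
    r shared a's key, r carried the diagnosis, and the group held exactly
    two diagnosis carriers (2 dx -> 1 dx resolution)."""
    from registrylink.core_model import extract_linkage_key, has_breast_cancer_dx

    for _ in range(40):
        a, b = random_instance(rng, n_keys=6, n_a=12, n_b=14)
        before = link_registries(a, b)
        for drop in range(len(b)):
            removed = b[drop]
            reduced = b[:drop] + b[drop + 1:]
            after = link_registries(a, reduced)
            newly = after.included_ids - before.included_ids
            group = [r for r in b if extract_linkage_key(r) == extract_linkage_key(removed)]
            n_dx = sum(has_breast_cancer_dx(r) for r in group)
            expects_new = has_breast_cancer_dx(removed) and n_dx == 2
            for rid in newly:
                rec = next(r for r in a if r.record_id == rid)
                assert extract_linkage_key(rec) == extract_linkage_key(removed)
            assert bool(newly) == (
                expects_new
                and any(
                    extract_linkage_key(r) == extract_linkage_key(removed)
                    and before.dispositions[r.record_id]
                    == Disposition.MATCHED_NONUNIQUE_AMBIGUOUS_OR_NO_DX
                    for r in a
                )
            )


def test_flow_report_counts_and_percentages():
    a = ([make_a("a1", *K(1))] + [make_a(f"c{i}", *K(99)) for i in range(2)]
         + [make_a("a2", *K(2)), make_a("a3", *K(3)), make_a("a4", *K(4))])
    b = [make_b("b1", *K(1), dx=True), make_b("b2", *K(2), dx=False),
         make_b("b3", *K(3), dx=True), make_b("b4", *K(3), dx=False)]
    report = flow_report(link_registries(a, b))
    assert report.total_a == 6 and report.excluded_nonunique_a == 2
    assert report.remaining == 4 and report.matched_in_b == 3
    assert report.unique_in_b == 2 and report.nonunique_in_b == 1
    assert report.included == 2
    report.validate()
    pct = report.percentages()
    assert pct["matched_of_remaining"]["percent"] == 75.0
    assert "final included" in report.to_text()


def test_flow_percentages_match_published_scale_counts():
    """Percentage computation at the published denominators: 9.6% matched
    of remaining, 77% diagnosis-confirmed among unique matches, 1.0%
    excluded for non-uniqueness."""
    report = FlowReport(
        total_a=214_596, excluded_nonunique_a=2_040, remaining=212_556,
        unmatched=192_107, matched_in_b=20_449, unique_in_b=18_724,
        unique_with_dx=14_499, unique_no_dx=4_225, nonunique_in_b=1_725,
        nonunique_resolved=1_155, nonunique_unresolved=570, included=15_654,
    )
    report.validate()
    pct = report.percentages()
    assert pct["matched_of_remaining"]["percent"] == 9.6
    assert round(pct["unique_with_dx_of_unique"]["percent"]) == 77
    assert round(pct["excluded_of_total"]["percent"]) == 1


def test_empty_result_yields_all_zero_report_with_flagged_percentages():
    report = flow_report(link_registries([], []))
    assert report.total_a == 0 and report.included == 0
    assert report.percentages()["included_of_total"]["undefined"]
    assert report.percentages()["included_of_total"]["percent"] is None


def test_linkage_commutes_with_pseudonymization(rng):
    """Running the engine on pseudonymized registries gives the same
    dispositions and pairs as on raw records."""
    for _ in range(10):
        a, b = random_instance(rng, n_keys=10, n_a=25, n_b=25)
        raw = link_registries(a, b)
        sent_a, sent_b = sender_prepare(a, b"s"), sender_prepare(b, b"s")
        fa = ttp_transform([r.pre_pseudonym for r in sent_a.rows], b"t")
        fb = ttp_transform([r.pre_pseudonym for r in sent_b.rows], b"t")
        ps_a, ps_b = receiver_combine(fa, sent_a.rows, fb, sent_b.rows)
        pseudo = link_registries(ps_a, ps_b)
        assert pseudo.dispositions == raw.dispositions
        assert sorted(pseudo.matched_pairs) == sorted(raw.matched_pairs)
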