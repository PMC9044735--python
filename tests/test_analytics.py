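"""Collision closed form, ground-truth performance metrics and the
case-control dilution model."""

import numpy as np
import pytest

from registrylink import (
    SimulationConfig,
    control_contamination,
    dilution_analysis,
    expected_collision_rate,
    generate_population,
    generate_registries,
    link_registries,
    linkage_performance,
    subgroup_inclusion,
)
from registrylink.linkage_engine import LinkageResult
from registrylink.synthetic_registry import GroundTruth, PersonTruth
from .conftest import key_of, make_a, make_b


def test_single_record_never_collides():
    assert expected_collision_rate(1, n_cells=10).per_record_probability == 0.0


def test_two_records_four_cells_expected_half_record_colliding():
    """Exhaustive oracle: of the 16 equally likely placements of 2 records
    into 4 cells, 4 put both in one cell, so P(collision) = 1/4 and the
    expected number of colliding records is 2 * 1/4 = 0.5."""
    est = expected_collision_rate(2, n_cells=4)
    assert est.per_record_probability == pytest.approx(0.25)
    assert est.expected_colliding_records == pytest.approx(0.5)


def test_closed_form_matches_placement_simulation():
    rng = np.random.default_rng(42)
    for n, c in [(50, 100), (200, 1000), (1000, 10_000)]:
        reps = 400
        colliding = np.empty(reps)
        for r in range(reps):
            cells = rng.integers(0, c, size=n)
            counts = np.bincount(cells, minlength=c)
            colliding[r] = n - counts[counts == 1].sum()
        expected = expected_collision_rate(n, n_cells=c).expected_colliding_records
        se = colliding.std(ddof=1) / np.sqrt(reps)
        assert abs(colliding.mean() - expected) < 3 * se


def test_nonuniform_cell_probabilities_generalize_the_uniform_form():
    uniform = expected_collision_rate(100, n_cells=50)
    via_probs = expected_collision_rate(100, cell_probs=[1 / 50] * 50)
    assert via_probs.per_record_probability == pytest.approx(
        uniform.per_record_probability
    )
    # in the sparse regime, concentrating mass raises collision probability
    sparse_uniform = expected_collision_rate(5, n_cells=50)
    sparse_skewed = expected_collision_rate(5, cell_probs=[0.5] + [0.5 / 49] * 49)
    assert sparse_skewed.per_record_probability > sparse_uniform.per_record_probability


def test_collision_rate_input_validation():
    with pytest.raises(ValueError):
        expected_collision_rate(0, n_cells=10)
    with pytest.raises(ValueError):
        expected_collision_rate(10)
    with pytest.raises(ValueError):
        expected_collision_rate(10, n_cells=5, cell_probs=[1.0])


def _truth(entries):
    return GroundTruth(persons={
        pid: PersonTruth(pid, a, b, dx, moved, keys_eq)
        for pid, a, b, dx, moved, keys_eq in entries
    })


def test_perfect_linkage_on_collision_free_instance():
    a = [make_a("a1", *key_of(1)), make_a("a2", *key_of(2))]
    b = [make_b("b1", *key_of(1)), make_b("b2", *key_of(2))]
    truth = _truth([
        ("p1", "a1", "b1", True, False, True),
        ("p2", "a2", "b2", True, False, True),
    ])
    perf = linkage_performance(link_registries(a, b), truth)
    assert perf.sensitivity == 1.0 and perf.ppv == 1.0
    assert perf.false_match_count == 0


def test_planted_false_match_lowers_ppv():
    """A unique key-match to the *wrong* diagnosis-bearing woman counts as
    a false match."""
    a = [make_a("a1", *key_of(1))]
    b = [make_b("b9", *key_of(1))]  # same key, different person, has X76
    truth = _truth([
        ("p1", "a1", None, True, None, False),
        ("p9", None, "b9", True, None, False),
    ])
    result = link_registries(a, b)
    perf = linkage_performance(result, truth)
    assert result.matched_pairs == [("a1", "b9")]
    assert perf.ppv == 0.0 and perf.false_match_count == 1


def test_empty_result_has_zero_sensitivity_when_true_pairs_exist():
    truth = _truth([("p1", "a1", "b1", True, False, True)])
    perf = linkage_performance(LinkageResult(), truth)
    assert perf.sensitivity == 0.0 and perf.ppv is None


def test_unknown_records_in_pairs_are_reported():
    truth = _truth([("p1", "a1", "b1", True, False, True)])
    bogus = LinkageResult(matched_pairs=[("zz", "b1")])
    with pytest.raises(ValueError, match="zz"):
        linkage_performance(bogus, truth)


def test_fast_and_oracle_linkage_score_identically(rng):
    from registrylink import brute_force_link
    from .conftest import random_instance

    a, b = random_instance(rng, n_keys=8, n_a=20, n_b=20)
    truth = _truth(
        [(f"pa{r.record_id}", r.record_id, None, True, None, False) for r in a]
        + [(f"pb{r.record_id}", None, r.record_id, False, None, False) for r in b]
    )
    p1 = linkage_performance(link_registries(a, b), truth)
    p2 = linkage_performance(brute_force_link(a, b), truth)
    assert p1 == p2


def test_subgroup_inclusion_probabilities():
    cohort = [make_a(f"a{i}", stage="I" if i < 6 else "IV") for i in range(10)]
    probs = subgroup_inclusion(cohort, {"a0", "a1", "a2", "a6"}, "stage")
    assert probs == {"I": 0.5, "IV": 0.25}


def test_control_contamination_counts_unlinked_true_cases():
    cfg = SimulationConfig(
        n_neighbourhoods=8, mean_households_per_neighbourhood=300,
        gp_recording_sensitivity=0.5, move_probability=0.0,
    )
    pop = generate_population(cfg, seed=31)
    reg_a, reg_b, truth = generate_registries(pop, cfg, seed=32)
    result = link_registries(reg_a, reg_b)
    f = control_contamination(truth, result)
    assert 0.0 <= f < 0.2
    unlinked_cases = sum(
        1 for t in truth.persons.values()
        if t.b_record_id and t.true_dx
        and t.person_id not in {truth.person_of(a) for a, _ in result.matched_pairs}
    )
    pool = sum(
        1 for t in truth.persons.values()
        if t.b_record_id
        and t.person_id not in {truth.person_of(a) for a, _ in result.matched_pairs}
    )
    assert f == pytest.approx(unlinked_cases / pool)


def test_dilution_preserves_the_null_and_the_uncontaminated_truth():
    assert dilution_analysis(2.0, 0.3, 0.0).observed_odds_ratio == pytest.approx(2.0)
    for f in (0.0, 0.1, 0.5, 1.0):
        assert dilution_analysis(1.0, 0.3, f).observed_odds_ratio == pytest.approx(1.0)


def test_dilution_attenuates_monotonically_toward_the_null():
    fs = np.linspace(0, 1, 11)
    ors = [dilution_analysis(2.0, 0.3, f).observed_odds_ratio for f in fs]
    assert all(x >= y - 1e-12 for x, y in zip(ors, ors[1:]))  # non-increasing
    assert ors[0] == pytest.approx(2.0) and ors[-1] == pytest.approx(1.0)
    # protective effects attenuate upward toward 1
    ors_prot = [dilution_analysis(0.5, 0.3, f).observed_odds_ratio for f in fs]
    assert all(x <= y + 1e-12 for x, y in zip(ors_prot, ors_prot[1:]))


def test_dilution_mixture_matches_subject_level_simulation():
    """Simulate 10^6 subjects: cases from the case exposure distribution,
    controls a mixture with fraction f of true cases."""
    rng = np.random.default_rng(5)
    res = dilution_analysis(2.0, 0.3, 0.2)
    n = 1_000_000
    exp_cases = rng.random(n) < res.case_exposure_prevalence
    is_contam = rng.random(n) < 0.2
    p_ctrl = np.where(is_contam, res.case_exposure_prevalence, 0.3)
    exp_ctrl = rng.random(n) < p_ctrl
    a, b = exp_cases.sum(), n - exp_cases.sum()
    c, d = exp_ctrl.sum(), n - exp_ctrl.sum()
    sim_or = (a / b) / (c / d)
    assert sim_or == pytest.approx(res.observed_odds_ratio, rel=0.02)


def test_dilution_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        dilution_analysis(2.0, 0.0, 0.1)
    with pytest.raises(ValueError):
        dilution_analysis(2.0, 1.0, 0.1)
    with pytest.raises(ValueError):
        dilution_analysis(-1.0, 0.3, 0.1)
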