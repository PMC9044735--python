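"""Synthetic paired health registries with ground-truth identity.

Emulates the two-registry setting so the whole pipeline is testable
without real data:

* a population of adult women living in pc4 neighbourhoods of ~2,000
  households each, with yearly residential mobility;
* registry A (cancer registry): every woman with an incident breast-cancer
  diagnosis inside the observation window, recorded with her address *at
  diagnosis* and clinical attributes (stage, surgery, therapy);
* registry B (primary-care registry): every woman registered at a covered
  GP practice (coverage ≈ 10% of practices), recorded with her address at
  the end-of-window snapshot; her GP records the ICPC X76 breast-cancer
  code with a configurable sensitivity < 1.

Ground truth maps every generated record back to its person, so linkage
sensitivity, PPV and mover-induced misses are measurable exactly.  A
separate deterministic *exact-flow fixture* constructs registries that
drive the linkage engine to prescribed branch counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable

import numpy as np

from .core_model import (
    CodeSystem,
    DiagnosisCode,
    RegistryId,
    Sex,
    SourceRecord,
)

__all__ = [
    "SimulationConfig",
    "Population",
    "PersonTruth",
    "GroundTruth",
    "generate_population",
    "generate_registries",
    "exact_flow_fixture",
    "EXAMPLE_FLOW_BRANCHES",
]

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the paired-registry simulation.

    Defaults encode the setting the toolkit targets: pc4 neighbourhoods of
    on average 2,000 households, a GP registry covering ~10% of practices,
    imperfect GP diagnosis recording, and yearly residential mobility.
    """

    n_neighbourhoods: int = 50
    mean_households_per_neighbourhood: float = 2000.0
    #: adult women per household on average (household -> cohort conversion)
    women_per_household: float = 1.0
    birth_year_range: tuple[int, int] = (1920, 1999)
    #: calendar years of registry observation; B's address snapshot is the
    #: final year
    observation_window: tuple[int, int] = (2000, 2016)
    #: (age_min, age_max, annual hazard) bands for incident breast cancer
    incidence_schedule: tuple[tuple[int, int, float], ...] = (
        (18, 44, 0.0005),
        (45, 59, 0.0020),
        (60, 74, 0.0030),
        (75, 120, 0.0035),
    )
    practices_per_neighbourhood: int = 2
    #: fraction of practices contributing to registry B
    coverage_fraction: float = 0.10
    #: P(X76 recorded | true diagnosis, person in B)
    gp_recording_sensitivity: float = 0.80
    #: per-year probability of moving to another neighbourhood
    move_probability: float = 0.05
    stage_distribution: tuple[tuple[str, float], ...] = (
        ("DCIS", 0.07), ("I", 0.41), ("II", 0.38), ("III", 0.09),
        ("IV", 0.04), ("Unknown", 0.01),
    )
    surgery_distribution: tuple[tuple[str, float], ...] = (
        ("breast_conserving", 0.49), ("amputation", 0.41),
        ("none", 0.09), ("unknown_other", 0.01),
    )
    axillary_dissection_prob: float = 0.38
    radiotherapy_prob: float = 0.60
    chemotherapy_prob: float = 0.37
    hormone_therapy_prob: float = 0.52
    year_bands: tuple[tuple[int, int], ...] = ((2000, 2004), (2005, 2009), (2010, 2016))
    age_bands: tuple[tuple[int, int], ...] = ((18, 44), (45, 59), (60, 74), (75, 120))

    def validate(self) -> None:
        if self.n_neighbourhoods < 1:
            raise ValueError("need at least one neighbourhood")
        if self.n_neighbourhoods > 9000:
            raise ValueError("at most 9000 pc4 neighbourhoods supported")
        probs = {
            "coverage_fraction": self.coverage_fraction,
            "gp_recording_sensitivity": self.gp_recording_sensitivity,
            "move_probability": self.move_probability,
            "axillary_dissection_prob": self.axillary_dissection_prob,
            "radiotherapy_prob": self.radiotherapy_prob,
            "chemotherapy_prob": self.chemotherapy_prob,
            "hormone_therapy_prob": self.hormone_therapy_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range reversed")
        if self.observation_window[0] > self.observation_window[1]:
            raise ValueError("observation_window reversed")
        for _, _, h in self.incidence_schedule:
            if not 0.0 <= h <= 1.0:
                raise ValueError("incidence hazards must be probabilities")


@dataclass
class Population:
    """Vectorized population: one row per woman.

    ``residence`` has shape (n_years, n_persons) holding the neighbourhood
    index occupied in each calendar year of the observation window.
    """

    config: SimulationConfig
    seed: int
    dob_ordinal: np.ndarray  # proleptic-Gregorian ordinals
    birth_year: np.ndarray
    practice: np.ndarray  # practice index
    residence: np.ndarray  # (n_years, n) neighbourhood indices
    years: np.ndarray  # calendar years covered by `residence`

    @property
    def n(self) -> int:
        return self.dob_ordinal.size

    def pc4_index_at(self, year: int) -> np.ndarray:
        y0 = int(self.years[0])
        i = min(max(int(year) - y0, 0), len(self.years) - 1)
        return self.residence[i]

    @staticmethod
    def pc4_label(index: int) -> str:
        return f"{1000 + int(index):04d}"


def generate_population(config: SimulationConfig, seed: int) -> Population:
    """Sample the female population with neighbourhoods, practices and a
    per-year residence history (seed-reproducible)."""
    config.validate()
    rng = np.random.default_rng(seed)
    mean_women = config.mean_households_per_neighbourhood * config.women_per_household
    sizes = rng.poisson(mean_women, size=config.n_neighbourhoods)
    n = int(sizes.sum())
    if n == 0:
        raise ValueError("configuration yields an empty population")
    home = np.repeat(np.arange(config.n_neighbourhoods), sizes)

    y0, y1 = config.birth_year_range
    start = date(y0, 1, 1).toordinal()
    end = date(y1, 12, 31).toordinal()
    dob = rng.integers(start, end + 1, size=n)
    # exact year lookup on unique ordinals only (dob spans ~30k distinct days)
    uniq, inv = np.unique(dob, return_inverse=True)
    uniq_years = np.array([date.fromordinal(int(o)).year for o in uniq])
    birth_year = uniq_years[inv]

    ppn = config.practices_per_neighbourhood
    practice = home * ppn + rng.integers(0, ppn, size=n)

    w0, w1 = config.observation_window
    years = np.arange(w0, w1 + 1)
    residence = np.empty((len(years), n), dtype=np.int32)
    residence[0] = home
    for i in range(1, len(years)):
        cur = residence[i - 1].copy()
        moves = rng.random(n) < config.move_probability
        n_m = int(moves.sum())
        if n_m and config.n_neighbourhoods > 1:
            # move to a uniformly chosen *other* neighbourhood
            new = rng.integers(0, config.n_neighbourhoods - 1, size=n_m)
            new[new >= cur[moves]] += 1
            cur[moves] = new
        residence[i] = cur
    return Population(
        config=config,
        seed=seed,
        dob_ordinal=dob,
        birth_year=birth_year,
        practice=practice.astype(np.int32),
        residence=residence,
        years=years,
    )


@dataclass(slots=True)
class PersonTruth:
    person_id: str
    a_record_id: str | None
    b_record_id: str | None
    true_dx: bool
    #: changed neighbourhood between diagnosis and the B snapshot
    #: (None when no diagnosis)
    moved: bool | None
    #: person appears in both registries with identical (dob, pc4) keys
    keys_equal: bool


@dataclass
class GroundTruth:
    """person_id -> record membership and true status, plus a record-id
    reverse index."""

    persons: dict[str, PersonTruth]
    by_record: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.by_record:
            for pid, t in self.persons.items():
                if t.a_record_id:
                    self.by_record[t.a_record_id] = pid
                if t.b_record_id:
                    self.by_record[t.b_record_id] = pid

    def person_of(self, record_id: str) -> str:
        return self.by_record[record_id]


def _band_label(bands: Iterable[tuple[int, int]], value: int) -> str:
    for lo, hi in bands:
        if lo <= value <= hi:
            return f"{lo}-{hi}"
    return "Unknown"


def _categorical(rng, dist: tuple[tuple[str, float], ...], size: int) -> np.ndarray:
    labels = [d[0] for d in dist]
    p = np.array([d[1] for d in dist], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=size, p=p)


def generate_registries(
    population: Population, config: SimulationConfig, seed: int
) -> tuple[list[SourceRecord], list[SourceRecord], GroundTruth]:
    """Derive registry A, registry B and ground truth from a population.

    A holds women with an incident diagnosis inside the window (address at
    diagnosis year); B holds women registered at covered practices (address
    at the window-end snapshot) with X76 recorded at the configured
    sensitivity.  Clinical attributes are sampled independently of linkage
    success so inclusion-bias tests have a clean null.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = population.n
    years = population.years

    # incident diagnosis year per woman (first event wins)
    dx_year = np.full(n, -1, dtype=np.int32)
    hazard_by_age = {}
    for lo, hi, h in config.incidence_schedule:
        for a in range(lo, hi + 1):
            hazard_by_age[a] = h
    for year in years:
        ages = year - population.birth_year
        uniq_ages, inv = np.unique(ages, return_inverse=True)
        haz = np.array([hazard_by_age.get(int(a), 0.0) for a in uniq_ages])
        events = (rng.random(n) < haz[inv]) & (dx_year < 0)
        dx_year[events] = int(year)

    # practice coverage
    n_practices = config.n_neighbourhoods * config.practices_per_neighbourhood
    n_covered = max(1, round(config.coverage_fraction * n_practices))
    covered = np.zeros(n_practices, dtype=bool)
    covered[rng.choice(n_practices, size=n_covered, replace=False)] = True
    in_b = covered[population.practice]

    snapshot_year = int(years[-1])
    pc4_snapshot = population.pc4_index_at(snapshot_year)

    # stable 2-letter suffixes per (person, neighbourhood)
    suffix_salt = rng.integers(0, 2**31)

    def postal(person: int, nbhd: int) -> str:
        h = (person * 1_000_003 + nbhd * 7919 + suffix_salt) % 676
        return f"{Population.pc4_label(nbhd)}{_LETTERS[h // 26]}{_LETTERS[h % 26]}"

    is_case = dx_year >= 0
    case_idx = np.flatnonzero(is_case)
    stages = _categorical(rng, config.stage_distribution, case_idx.size)
    surgeries = _categorical(rng, config.surgery_distribution, case_idx.size)
    axillary = rng.random(case_idx.size) < config.axillary_dissection_prob
    radio = rng.random(case_idx.size) < config.radiotherapy_prob
    chemo = rng.random(case_idx.size) < config.chemotherapy_prob
    hormone = rng.random(case_idx.size) < config.hormone_therapy_prob
    x76_recorded = rng.random(case_idx.size) < config.gp_recording_sensitivity
    x76_by_person = dict(zip(case_idx.tolist(), x76_recorded.tolist()))

    registry_a: list[SourceRecord] = []
    truth: dict[str, PersonTruth] = {}
    dob_dates = [date.fromordinal(int(o)) for o in population.dob_ordinal]

    for j, p in enumerate(case_idx.tolist()):
        y = int(dx_year[p])
        nb_dx = int(population.pc4_index_at(y)[p])
        age = y - int(population.birth_year[p])
        rid = f"A{p:08d}"
        registry_a.append(
            SourceRecord(
                record_id=rid,
                registry_id=RegistryId.A_CANCER,
                sex=Sex.FEMALE,
                date_of_birth=dob_dates[p],
                postal_code=postal(p, nb_dx),
                diagnosis_codes=frozenset(
                    {DiagnosisCode(CodeSystem.ICD10, f"C50.{p % 10}", y)}
                ),
                attributes={
                    "diagnosis_year": y,
                    "year_band": _band_label(config.year_bands, y),
                    "age_band": _band_label(config.age_bands, age),
                    "stage": str(stages[j]),
                    "surgery": str(surgeries[j]),
                    "axillary_dissection": bool(axillary[j]),
                    "radiotherapy": bool(radio[j]),
                    "chemotherapy": bool(chemo[j]),
                    "hormone_therapy": bool(hormone[j]),
                },
            )
        )

    registry_b: list[SourceRecord] = []
    b_idx = np.flatnonzero(in_b)
    reg_years = rng.integers(int(years[0]), snapshot_year + 1, size=b_idx.size)
    last_mo = rng.integers(1, 13, size=b_idx.size)
    for j, p in enumerate(b_idx.tolist()):
        nb = int(pc4_snapshot[p])
        rid = f"B{p:08d}"
        codes: set[DiagnosisCode] = set()
        if is_case[p] and x76_by_person[p]:
            codes.add(DiagnosisCode(CodeSystem.ICPC1, "X76", int(dx_year[p])))
        registry_b.append(
            SourceRecord(
                record_id=rid,
                registry_id=RegistryId.B_PRIMARY_CARE,
                sex=Sex.FEMALE,
                date_of_birth=dob_dates[p],
                postal_code=postal(p, nb),
                diagnosis_codes=frozenset(codes),
                attributes={
                    "practice_id": f"P{int(population.practice[p]):05d}",
                    "registration_date": f"{int(reg_years[j])}-01-01",
                    "last_encounter_date": f"{snapshot_year}-{int(last_mo[j]):02d}-15",
                    "last_encounter_codes": "X76" if codes else "A97",
                },
            )
        )

    in_b_set = set(b_idx.tolist())
    for p in range(n):
        has_a = bool(is_case[p])
        has_b = p in in_b_set
        if not (has_a or has_b):
            continue
        moved = None
        keys_equal = False
        if has_a:
            nb_dx = int(population.pc4_index_at(int(dx_year[p]))[p])
            moved = nb_dx != int(pc4_snapshot[p])
            keys_equal = has_b and not moved
        truth[f"P{p:08d}"] = PersonTruth(
            person_id=f"P{p:08d}",
            a_record_id=f"A{p:08d}" if has_a else None,
            b_record_id=f"B{p:08d}" if has_b else None,
            true_dx=has_a,
            moved=moved,
            keys_equal=keys_equal,
        )
    return registry_a, registry_b, GroundTruth(persons=truth)


# ---------------------------------------------------------------------------
# Exact-flow fixture
# ---------------------------------------------------------------------------

#: A realistic national-scale example: ~215k cancer-registry records, ~10%
#: GP-registry coverage, 77% GP recording among unique matches.
EXAMPLE_FLOW_BRANCHES: dict[str, int] = {
    "total_a": 214_596,
    "excluded_nonunique_a": 2_040,
    "matched_in_b": 20_449,
    "unique_in_b": 18_724,
    "unique_with_dx": 14_499,
    "nonunique_resolved": 1_155,
}


def _check_branches(bc: dict[str, int]) -> dict[str, int]:
    required = set(EXAMPLE_FLOW_BRANCHES)
    missing = required - set(bc)
    if missing:
        raise ValueError(f"missing branch counts: {sorted(missing)}")
    d = {k: int(bc[k]) for k in required}
    d["remaining"] = d["total_a"] - d["excluded_nonunique_a"]
    d["unmatched"] = d["remaining"] - d["matched_in_b"]
    d["nonunique_in_b"] = d["matched_in_b"] - d["unique_in_b"]
    d["nonunique_unresolved"] = d["nonunique_in_b"] - d["nonunique_resolved"]
    identities = {
        "all branch counts must be non-negative": all(v >= 0 for v in d.values()),
        "excluded_nonunique_a <= total_a": d["excluded_nonunique_a"] <= d["total_a"],
        "matched_in_b <= remaining": d["matched_in_b"] <= d["remaining"],
        "unique_in_b <= matched_in_b": d["unique_in_b"] <= d["matched_in_b"],
        "unique_with_dx <= unique_in_b": d["unique_with_dx"] <= d["unique_in_b"],
        "nonunique_resolved <= nonunique_in_b":
            d["nonunique_resolved"] <= d["nonunique_in_b"],
        "excluded_nonunique_a != 1 (colliding groups have >= 2 records)":
            d["excluded_nonunique_a"] != 1,
    }
    failed = [name for name, ok in identities.items() if not ok]
    if failed:
        raise ValueError("inconsistent branch counts: " + "; ".join(failed))
    return d


def exact_flow_fixture(
    branch_counts: dict[str, int] | None = None, seed: int = 0
) -> tuple[list[SourceRecord], list[SourceRecord]]:
    """Construct registries that drive :func:`~registrylink.linkage_engine.
    link_registries` to the requested branch counts exactly.

    Branch counts are validated against the flow identities first; an
    inconsistent request is refused naming the violated identity.  Distinct
    linkage keys are laid out via a bijective scrambling of a
    (day-of-birth x pc4) grid, so the fixture scales to national-size
    cohorts in seconds.  Unresolvable non-unique B-groups alternate between
    the two sub-cases (two diagnosis-bearing candidates / none).
    """
    d = _check_branches(branch_counts or EXAMPLE_FLOW_BRANCHES)
    rng = np.random.default_rng(seed)

    n_days, n_pc4 = 29_220, 9_000  # ~80 birth years x pc4 space
    space = n_days * n_pc4
    base = date(1920, 1, 1).toordinal()
    counter = 0

    def next_key() -> tuple[date, str]:
        nonlocal counter
        idx = (counter * 2_654_435_761) % space
        counter += 1
        return (
            date.fromordinal(base + idx % n_days),
            f"{1000 + idx // n_days:04d}",
        )

    a_records: list[SourceRecord] = []
    b_records: list[SourceRecord] = []
    n_a = 0
    n_b = 0

    def add_a(dob: date, pc4: str) -> None:
        nonlocal n_a
        yr = 2000 + n_a % 17
        a_records.append(
            SourceRecord(
                record_id=f"A{n_a:07d}",
                registry_id=RegistryId.A_CANCER,
                sex=Sex.FEMALE,
                date_of_birth=dob,
                postal_code=pc4 + _LETTERS[n_a % 26] + _LETTERS[(n_a // 26) % 26],
                diagnosis_codes=frozenset(
                    {DiagnosisCode(CodeSystem.ICD10, f"C50.{n_a % 10}", yr)}
                ),
                attributes={"diagnosis_year": yr},
            )
        )
        n_a += 1

    def add_b(dob: date, pc4: str, with_dx: bool) -> None:
        nonlocal n_b
        codes = (
            frozenset({DiagnosisCode(CodeSystem.ICPC1, "X76", 2000 + n_b % 17)})
            if with_dx
            else frozenset()
        )
        b_records.append(
            SourceRecord(
                record_id=f"B{n_b:07d}",
                registry_id=RegistryId.B_PRIMARY_CARE,
                sex=Sex.FEMALE,
                date_of_birth=dob,
                postal_code=pc4,
                diagnosis_codes=codes,
                attributes={
                    "practice_id": f"P{n_b % 500:05d}",
                    "registration_date": "2000-01-01",
                    "last_encounter_date": "2016-06-15",
                    "last_encounter_codes": "X76" if with_dx else "A97",
                },
            )
        )
        n_b += 1

    # colliding A-groups (pairs; one triple if the count is odd)
    excl = d["excluded_nonunique_a"]
    while excl > 0:
        dob, pc4 = next_key()
        size = 3 if excl == 3 else 2
        for _ in range(size):
            add_a(dob, pc4)
        excl -= size

    for _ in range(d["unmatched"]):
        dob, pc4 = next_key()
        add_a(dob, pc4)

    for i in range(d["unique_in_b"]):
        dob, pc4 = next_key()
        add_a(dob, pc4)
        add_b(dob, pc4, with_dx=i < d["unique_with_dx"])

    for _ in range(d["nonunique_resolved"]):
        dob, pc4 = next_key()
        add_a(dob, pc4)
        add_b(dob, pc4, with_dx=True)
        add_b(dob, pc4, with_dx=False)

    for i in range(d["nonunique_unresolved"]):
        dob, pc4 = next_key()
        add_a(dob, pc4)
        ambiguous = i % 2 == 0
        add_b(dob, pc4, with_dx=ambiguous)
        add_b(dob, pc4, with_dx=ambiguous)

    rng.shuffle(a_records)
    rng.shuffle(b_records)
    return a_records, b_records
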