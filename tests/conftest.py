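"""Shared builders for handcrafted registry instances."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from registrylink import (
    CodeSystem,
    DiagnosisCode,
    RegistryId,
    Sex,
    SourceRecord,
)


def make_a(rid, dob=date(1957, 5, 14), pc="1234AB", dx=True, sex=Sex.FEMALE, **attrs):
    codes = (
        frozenset({DiagnosisCode(CodeSystem.ICD10, "C50.4", 2005)})
        if dx
        else frozenset()
    )
    return SourceRecord(rid, RegistryId.A_CANCER, sex, dob, pc, codes, dict(attrs))


def make_b(rid, dob=date(1957, 5, 14), pc="1234AB", dx=True, sex=Sex.FEMALE, **attrs):
    codes = (
        frozenset({DiagnosisCode(CodeSystem.ICPC1, "X76", 2006)})
        if dx
        else frozenset()
    )
    return SourceRecord(rid, RegistryId.B_PRIMARY_CARE, sex, dob, pc, codes, dict(attrs))


def key_of(i: int) -> tuple[date, str]:
    """Deterministic small-keyspace enumeration for tests."""
    return date(1950, 1, 1) + timedelta(days=i % 400), f"{1000 + i // 400:04d}"


def random_instance(rng: np.random.Generator, n_keys: int = 12,
                    n_a: int = 30, n_b: int = 30):
    """A random small two-registry instance over a tight keyspace, so
    collisions, disambiguation and unmatched branches all occur."""
    a = []
    for i in range(n_a):
        dob, pc = key_of(int(rng.integers(n_keys)))
        a.append(make_a(f"a{i}", dob, pc, dx=True))
    b = []
    for i in range(n_b):
        dob, pc = key_of(int(rng.integers(n_keys)))
        b.append(make_b(f"b{i}", dob, pc, dx=bool(rng.random() < 0.6)))
    return a, b


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
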