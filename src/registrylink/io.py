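"""CSV/JSON readers and writers, run configuration, and the end-to-end
pipeline.

Registry CSV dialect: UTF-8 with a header row and columns ``record_id``,
``registry_id``, ``sex``, ``date_of_birth`` (ISO-8601), ``postal_code``,
an optional inline ``diagnosis_codes`` column
(``"ICD10:C50.4:2005;ICPC1:X76:2006"``), and any further named columns as
clinical attributes.  Diagnoses may instead (or additionally) come from a
companion long-format CSV with columns ``record_id, code_system, code,
year``.

Privacy contract of the pipeline: once records pass the pseudonymization
stage, no file written downstream contains a raw date of birth or a
6-character postal code, and secrets are never serialized into outputs or
logs.  Record-level error messages reference record ids only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .core_model import (
    POSTAL_CODE_RE,
    CodeSystem,
    DiagnosisCode,
    RegistryId,
    Sex,
    SourceRecord,
)
from .linkage_engine import FlowReport, flow_report, link_registries
from .pseudonymization import (
    PseudonymizedRecord,
    SenderRow,
    receiver_combine,
    sender_prepare,
    ttp_transform,
)
from .quality_assessment import InclusionTable, inclusion_table
from .synthetic_registry import (
    SimulationConfig,
    generate_population,
    generate_registries,
)
from . import analytics

__all__ = [
    "RegistryReadError",
    "ReadReport",
    "RunConfig",
    "read_registry",
    "write_registry",
    "write_flow_report",
    "write_matched_pairs",
    "write_inclusion_table",
    "write_json",
    "read_key_file",
    "run_pipeline",
]

_BASE_COLUMNS = ["record_id", "registry_id", "sex", "date_of_birth", "postal_code"]


class RegistryReadError(ValueError):
    pass


@dataclass(slots=True)
class ReadReport:
    n_rows: int
    errors: list[tuple[int, str, str]] = field(default_factory=list)  # (row, record_id, reason)

    @property
    def error_fraction(self) -> float:
        return len(self.errors) / self.n_rows if self.n_rows else 0.0


def _parse_codes(spec: str) -> frozenset[DiagnosisCode]:
    codes = set()
    for part in str(spec).split(";"):
        part = part.strip()
        if not part:
            continue
        system, code, year = part.split(":")
        codes.add(DiagnosisCode(CodeSystem(system), code, int(year)))
    return frozenset(codes)


def _format_codes(codes: frozenset[DiagnosisCode]) -> str:
    return ";".join(
        f"{c.system.value}:{c.code}:{c.year}"
        for c in sorted(codes, key=lambda c: (c.system.value, c.code, c.year))
    )


def read_registry(
    path: str | Path,
    diagnoses_path: str | Path | None = None,
    max_error_fraction: float = 0.01,
) -> tuple[list[SourceRecord], ReadReport]:
    """Read and validate a registry CSV (optionally with a companion
    long-format diagnosis CSV).

    Malformed rows are collected into the report, not silently dropped;
    duplicate record ids abort immediately, and the whole read aborts when
    the malformed fraction exceeds ``max_error_fraction`` (default 1%).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryReadError(f"{path}: missing columns {missing}")
    dup = df["record_id"][df["record_id"].duplicated()]
    if not dup.empty:
        raise RegistryReadError(
            f"{path}: duplicate record_id values, e.g. {dup.iloc[0]!r}"
        )

    extra_dx: dict[str, set[DiagnosisCode]] = {}
    if diagnoses_path is not None:
        ddf = pd.read_csv(diagnoses_path, dtype=str, keep_default_na=False)
        for _, row in ddf.iterrows():
            extra_dx.setdefault(row["record_id"], set()).add(
                DiagnosisCode(
                    CodeSystem(row["code_system"]), row["code"], int(row["year"])
                )
            )

    attr_cols = [
        c for c in df.columns if c not in _BASE_COLUMNS and c != "diagnosis_codes"
    ]
    records: list[SourceRecord] = []
    report = ReadReport(n_rows=len(df))
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        rid = getattr(row, "record_id")
        try:
            dob = date.fromisoformat(getattr(row, "date_of_birth"))
        except ValueError:
            report.errors.append((i, rid, "date of birth not ISO-8601"))
            continue
        pc = getattr(row, "postal_code")
        if not POSTAL_CODE_RE.match(pc):
            report.errors.append((i, rid, "malformed postal code"))
            continue
        try:
            registry_id = RegistryId(getattr(row, "registry_id"))
            sex = Sex(getattr(row, "sex"))
        except ValueError as err:
            report.errors.append((i, rid, str(err)))
            continue
        codes: set[DiagnosisCode] = set(extra_dx.get(rid, set()))
        if "diagnosis_codes" in df.columns:
            try:
                codes |= _parse_codes(getattr(row, "diagnosis_codes"))
            except (ValueError, KeyError):
                report.errors.append((i, rid, "malformed diagnosis_codes"))
                continue
        attributes = {c: getattr(row, c) for c in attr_cols}
        records.append(
            SourceRecord(
                record_id=rid,
                registry_id=registry_id,
                sex=sex,
                date_of_birth=dob,
                postal_code=pc,
                diagnosis_codes=frozenset(codes),
                attributes=attributes,
            )
        )
    if report.error_fraction > max_error_fraction:
        raise RegistryReadError(
            f"{path}: {len(report.errors)}/{report.n_rows} malformed rows "
            f"exceeds the tolerance of {max_error_fraction:.1%}"
        )
    return records, report


def write_registry(records: Sequence[SourceRecord], path: str | Path) -> None:
    rows = []
    attr_keys: list[str] = []
    for r in records:
        for k in r.attributes:
            if k not in attr_keys:
                attr_keys.append(k)
    for r in records:
        row = {
            "record_id": r.record_id,
            "registry_id": r.registry_id.value,
            "sex": r.sex.value,
            "date_of_birth": r.date_of_birth.isoformat(),
            "postal_code": r.postal_code,
            "diagnosis_codes": _format_codes(r.diagnosis_codes),
        }
        for k in attr_keys:
            row[k] = r.attributes.get(k, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_BASE_COLUMNS[:1] + _BASE_COLUMNS[1:] + ["diagnosis_codes"] + attr_keys).to_csv(
        path, index=False
    )


# --- pseudonymization-stage files (the "data files sent between parties") ---

def write_pseudonym_list(pseudonyms: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"pseudonym": list(pseudonyms)}).to_csv(path, index=False)


def read_pseudonym_list(path: str | Path) -> list[str]:
    return pd.read_csv(path, dtype=str)["pseudonym"].tolist()


def write_sender_payload(rows: Sequence[SenderRow], path: str | Path) -> None:
    """Row-ordered aggregated QIDs + clinical payload (no pseudonyms, no
    raw quasi-identifiers) for the receiving party."""
    pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "registry_id": r.registry_id.value,
                "sex": r.sex.value,
                "birth_year": r.qid.birth_year,
                "birth_quarter": r.qid.birth_quarter,
                "pc4": r.qid.pc4,
                "diagnosis_codes": _format_codes(r.diagnosis_codes),
                "attributes": json.dumps(r.attributes, sort_keys=True, default=str),
            }
            for r in rows
        ]
    ).to_csv(path, index=False)


def write_pseudonymized_registry(
    records: Sequence[PseudonymizedRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "pseudonym": r.pseudonym,
                "record_id": r.record_id,
                "registry_id": r.registry_id.value,
                "sex": r.sex.value,
                "birth_year": r.qid.birth_year,
                "birth_quarter": r.qid.birth_quarter,
                "pc4": r.qid.pc4,
                "diagnosis_codes": _format_codes(r.diagnosis_codes),
                "attributes": json.dumps(r.attributes, sort_keys=True, default=str),
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_pseudonymized_registry(path: str | Path) -> list[PseudonymizedRecord]:
    from .core_model import AggregatedQID

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PseudonymizedRecord(
                pseudonym=row.pseudonym,
                record_id=row.record_id,
                registry_id=RegistryId(row.registry_id),
                sex=Sex(row.sex),
                qid=AggregatedQID(
                    birth_year=int(row.birth_year),
                    birth_quarter=int(row.birth_quarter),
                    pc4=row.pc4,
                ),
                diagnosis_codes=_parse_codes(row.diagnosis_codes),
                attributes=json.loads(row.attributes),
            )
        )
    return out


# --- report writers ---------------------------------------------------------

def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def write_flow_report(
    report: FlowReport, json_path: str | Path, text_path: str | Path | None = None
) -> None:
    write_json(report.to_dict(), json_path)
    if text_path is not None:
        Path(text_path).write_text(report.to_text() + "\n")


def write_matched_pairs(
    pairs: Sequence[tuple[str, str]], path: str | Path
) -> None:
    pd.DataFrame(pairs, columns=["record_id_a", "record_id_b"]).to_csv(
        path, index=False
    )


def write_inclusion_table(table: InclusionTable, path: str | Path) -> None:
    rows = []
    for b in table.blocks:
        for r in b.rows:
            rows.append(
                {
                    "characteristic": b.name,
                    "category": r.category,
                    "n_total": r.n_total,
                    "n_included": r.n_included,
                    "pct_included": r.pct_included,
                    "statistic": b.statistic,
                    "df": b.df,
                    "p_value": b.p_value,
                    "notes": "; ".join(b.notes),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_key_file(path: str | Path) -> bytes:
    data = Path(path).read_bytes().strip()
    if not data:
        raise ValueError(f"key file {path} is empty")
    return data


# --- run configuration and pipeline ----------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Secrets are referenced by file path only and are never echoed into the
    manifest or any other output.
    """

    out_dir: str
    sender_key_file: str
    ttp_key_file: str
    seed: int = 0
    #: simulate when set; otherwise read registry_a/b paths
    simulation: SimulationConfig | None = None
    registry_a: str | None = None
    registry_b: str | None = None
    diagnoses_a: str | None = None
    diagnoses_b: str | None = None
    characteristics: tuple[str, ...] = (
        "year_band",
        "age_band",
        "stage",
        "surgery",
    )
    max_error_fraction: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dc_fields(cls)}})
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if isinstance(cfg.characteristics, list):
            cfg.characteristics = tuple(cfg.characteristics)
        return cfg


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/read -> pseudonymize -> link -> assess -> analyze and
    write all artifacts plus a reproducibility manifest.

    Returns the manifest dict.  Deterministic stages are byte-identical
    across reruns with the same configuration and seed.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "input_checksums": {},
        "stages": [],
    }
    manifest_path = out / "manifest.json"

    def stage(name: str, outputs: list[str], status: str = "completed") -> None:
        manifest["stages"].append(
            {"name": name, "status": status, "outputs": sorted(outputs)}
        )
        write_json(manifest, manifest_path)

    try:
        # secrets first: a missing key file fails before any registry is read
        sender_secret = read_key_file(config.sender_key_file)
        ttp_secret = read_key_file(config.ttp_key_file)

        truth = None
        if config.simulation is not None:
            pop = generate_population(config.simulation, config.seed)
            reg_a, reg_b, truth = generate_registries(
                pop, config.simulation, config.seed + 1
            )
            input_dir = out / "input"
            input_dir.mkdir(exist_ok=True)
            write_registry(reg_a, input_dir / "registry_a.csv")
            write_registry(reg_b, input_dir / "registry_b.csv")
            stage(
                "simulate",
                [str(input_dir / "registry_a.csv"), str(input_dir / "registry_b.csv")],
            )
        else:
            if not config.registry_a or not config.registry_b:
                raise RegistryReadError(
                    "either a simulation block or both registry paths are required"
                )
            manifest["input_checksums"][config.registry_a] = _sha256(config.registry_a)
            manifest["input_checksums"][config.registry_b] = _sha256(config.registry_b)
            reg_a, _ = read_registry(
                config.registry_a, config.diagnoses_a, config.max_error_fraction
            )
            reg_b, _ = read_registry(
                config.registry_b, config.diagnoses_b, config.max_error_fraction
            )
            stage("read", [])

        sent_a = sender_prepare(reg_a, sender_secret)
        sent_b = sender_prepare(reg_b, sender_secret)
        final_a = ttp_transform([r.pre_pseudonym for r in sent_a.rows], ttp_secret)
        final_b = ttp_transform([r.pre_pseudonym for r in sent_b.rows], ttp_secret)
        ps_a, ps_b = receiver_combine(final_a, sent_a.rows, final_b, sent_b.rows)
        write_pseudonymized_registry(ps_a, out / "pseudonymized_a.csv")
        write_pseudonymized_registry(ps_b, out / "pseudonymized_b.csv")
        write_json(
            {
                "registry_a_errors": sent_a.errors,
                "registry_b_errors": sent_b.errors,
            },
            out / "pseudonymization_errors.json",
        )
        stage(
            "pseudonymize",
            [
                str(out / "pseudonymized_a.csv"),
                str(out / "pseudonymized_b.csv"),
                str(out / "pseudonymization_errors.json"),
            ],
        )

        result = link_registries(ps_a, ps_b)
        report = flow_report(result)
        write_flow_report(report, out / "flow_report.json", out / "flow_report.txt")
        write_matched_pairs(result.matched_pairs, out / "matched_pairs.csv")
        stage(
            "link",
            [
                str(out / "flow_report.json"),
                str(out / "flow_report.txt"),
                str(out / "matched_pairs.csv"),
            ],
        )

        table = inclusion_table(
            ps_a, {a for a, _ in result.matched_pairs}, list(config.characteristics)
        )
        write_inclusion_table(table, out / "inclusion_table.csv")
        stage("assess", [str(out / "inclusion_table.csv")])

        if truth is not None:
            perf = analytics.linkage_performance(result, truth)
            metrics = {
                "sensitivity": perf.sensitivity,
                "ppv": perf.ppv,
                "n_true_linkable_pairs": perf.n_true_linkable_pairs,
                "n_reported_pairs": perf.n_reported_pairs,
                "false_match_count": perf.false_match_count,
                "control_contamination": analytics.control_contamination(
                    truth, result
                ),
            }
            write_json(metrics, out / "metrics.json")
            stage("analyze", [str(out / "metrics.json")])
    except Exception as err:
        stage("failed", [], status=f"error: {type(err).__name__}")
        raise
    return manifest
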