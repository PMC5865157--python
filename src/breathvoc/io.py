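"""Delimited-text readers/writers and the run configuration.

All tables are comma-delimited UTF-8 with a single header line: compound
libraries, per-platform peak tables, alkane ladders, calibration series
and annotation reports. Unit-resolution integer m/z and small libraries
make binary formats unnecessary. Readers validate field counts row by
row, so silently truncated files are rejected rather than half-read.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict

from . import chem
from .annotate import AnnotationConfig
from .errors import FormulaError, InputError
from .records import (AnnotationResult, ChemClass, CompoundRecord,
                      EvidenceRecord, Peak, PeakTable, Platform, Tier)

logger = logging.getLogger("breathvoc")

__all__ = [
    "RunConfig", "read_compound_library", "write_compound_library",
    "read_peak_table", "write_peak_table", "read_alkane_ladder",
    "write_annotation_report", "read_annotation_report",
]


class RunConfig(BaseModel):
    """Whole-run configuration, serialisable to a single YAML file.

    Defaults reproduce the documented behaviour; unknown keys are
    rejected so a typo cannot silently fall back to a default.
    """

    model_config = ConfigDict(extra="forbid")

    mz_tolerance: float = 0.3
    ri_tolerance: float = 15.0
    gate_threshold: int = 800
    intensity_floor: float = 0.0
    contradiction_min_peaks: int = 3
    max_hydrates: int = 2
    reagent: str = "water"
    dimer_audit: bool = False

    def to_annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(**self.model_dump())

    def fingerprint(self) -> str:
        """Short stable digest of the configuration, embedded in reports."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def _read_rows(path, required: Sequence[str],
               optional: Sequence[str] = ()) -> tuple[list[str], list[dict]]:
    """Read a delimited table, enforcing header and per-row field counts."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    reader = csv.reader(text.splitlines())
    try:
        header = [h.strip() for h in next(reader)]
    except StopIteration:
        raise InputError(f"{path}: empty file, header expected") from None
    missing = [c for c in required if c not in header]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    rows = []
    for lineno, row in enumerate(reader, start=2):
        if not row or not any(f.strip() for f in row):
            continue
        if len(row) != len(header):
            raise InputError(
                f"{path} line {lineno}: {len(row)} fields, header has "
                f"{len(header)} (truncated or malformed row)"
            )
        rows.append({"_lineno": lineno,
                     **{h: v.strip() for h, v in zip(header, row)}})
    return header, rows


def read_compound_library(path) -> list[CompoundRecord]:
    """Read a compound library table.

    Columns: ``name, formula, chem_class`` required; ``carbon_count``,
    ``reference_ri``, ``proton_affinity``, ``substituted_benzene``
    optional. Duplicate names and malformed formulas are errors with the
    offending line number.
    """
    _, rows = _read_rows(path, ["name", "formula", "chem_class"])
    records, seen = [], set()
    for row in rows:
        lineno = row["_lineno"]
        name = row["name"]
        if not name:
            raise InputError(f"{path} line {lineno}: empty compound name")
        if name in seen:
            raise InputError(f"{path} line {lineno}: duplicate compound {name!r}")
        seen.add(name)
        if not row["chem_class"]:
            raise InputError(f"{path} line {lineno}: missing chemical class")
        try:
            records.append(CompoundRecord(
                name=name,
                formula=chem.parse_formula(row["formula"]),
                chem_class=ChemClass(row["chem_class"]),
                carbon_count=int(row["carbon_count"])
                if row.get("carbon_count") else None,
                reference_ri=float(row["reference_ri"])
                if row.get("reference_ri") else None,
                proton_affinity=float(row["proton_affinity"])
                if row.get("proton_affinity") else None,
                substituted_benzene=row.get("substituted_benzene", "")
                .lower() in ("true", "1", "yes"),
            ))
        except (FormulaError, InputError, ValueError) as exc:
            raise InputError(f"{path} line {lineno}: {exc}") from exc
    logger.info("read %d compounds from %s", len(records), path)
    return records


def write_compound_library(records: Sequence[CompoundRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "formula", "chem_class", "carbon_count",
                    "reference_ri", "proton_affinity", "substituted_benzene"])
        for r in records:
            w.writerow([
                r.name, chem.format_formula(r.formula), r.chem_class.value,
                r.carbon_count,
                "" if r.reference_ri is None else r.reference_ri,
                "" if r.proton_affinity is None else r.proton_affinity,
                str(r.substituted_benzene).lower(),
            ])


def read_peak_table(path, platform: Optional[str] = None) -> PeakTable:
    """Read an observed peak table.

    Columns: ``mz, intensity`` required; ``platform``, ``sample``,
    ``retention_time``, ``retention_index`` optional. A retention-time
    column on a SIFT table draws a warning and is ignored — SIFT-MS has
    no chromatography.
    """
    header, rows = _read_rows(path, ["mz", "intensity"])
    if platform is None:
        platforms = {r.get("platform", "") for r in rows}
        platforms.discard("")
        if len(platforms) != 1:
            raise InputError(
                f"{path}: pass platform= or provide a single-valued "
                f"platform column (found {sorted(platforms)})"
            )
        platform = platforms.pop()
    plat = Platform(platform)
    sift_with_rt = (not plat.has_chromatography
                    and any(r.get("retention_time") for r in rows))
    if sift_with_rt:
        warnings.warn(
            f"{path}: retention-time column on a {plat.value} table ignored "
            "(no chromatographic separation)", stacklevel=2)
    peaks = []
    sample = "sample"
    for row in rows:
        lineno = row["_lineno"]
        try:
            intensity = float(row["intensity"])
            if intensity < 0:
                raise InputError(f"negative intensity {intensity}")
            rt = (float(row["retention_time"])
                  if row.get("retention_time") and plat.has_chromatography
                  else None)
            ri = (float(row["retention_index"])
                  if row.get("retention_index") and plat.has_chromatography
                  else None)
            peaks.append(Peak(mz=float(row["mz"]), intensity=intensity,
                              retention_time=rt, retention_index=ri))
        except (InputError, ValueError) as exc:
            raise InputError(f"{path} line {lineno}: {exc}") from exc
        sample = row.get("sample") or sample
    logger.info("read %d %s peaks from %s", len(peaks), plat.value, path)
    return PeakTable(platform=plat, peaks=peaks, sample_id=sample)


def write_peak_table(table: PeakTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["platform", "sample", "retention_time",
                    "retention_index", "mz", "intensity"])
        for p in table.peaks:
            w.writerow([
                table.platform.value, table.sample_id,
                "" if p.retention_time is None else p.retention_time,
                "" if p.retention_index is None else p.retention_index,
                p.mz, p.intensity,
            ])


def read_alkane_ladder(path) -> list[tuple[int, float]]:
    """Read a C5-C20 n-alkane ladder: columns carbon_number, retention_time."""
    _, rows = _read_rows(path, ["carbon_number", "retention_time"])
    ladder = []
    for row in rows:
        try:
            ladder.append((int(row["carbon_number"]),
                           float(row["retention_time"])))
        except ValueError as exc:
            raise InputError(f"{path} line {row['_lineno']}: {exc}") from exc
    return sorted(ladder)


_REPORT_COLUMNS = [
    "feature_id", "candidate", "tier", "ambiguity_set", "platform",
    "matched", "contradicts", "ri_match", "matched_ions",
]


def _ions_to_str(ions) -> str:
    return ";".join(f"{p}:{o!r}:{i!r}" for p, o, i in ions)


def _ions_from_str(text: str):
    out = []
    for part in text.split(";"):
        if not part:
            continue
        p, o, i = part.split(":")
        out.append((int(p), float(o), float(i)))
    return out


def write_annotation_report(results: Sequence[AnnotationResult], path,
                            config: Optional[RunConfig] = None) -> None:
    """One row per (feature, candidate, platform), with the config
    fingerprint on a leading comment line for reproducibility."""
    config = config or RunConfig()
    with open(path, "w", newline="") as fh:
        fh.write(f"# breathvoc-config {config.fingerprint()}\n")
        w = csv.writer(fh)
        w.writerow(_REPORT_COLUMNS)
        for res in results:
            common = [res.feature_id, res.candidate.name, res.tier.value,
                      ";".join(res.ambiguity_set)]
            if not res.evidence:
                w.writerow(common + ["", "", "", "", ""])
            for ev in res.evidence:
                w.writerow(common + [
                    ev.platform.value, ev.matched, ev.contradicts,
                    "" if ev.ri_match is None else ev.ri_match,
                    _ions_to_str(ev.matched_ions),
                ])


def read_annotation_report(path) -> tuple[list[dict], str]:
    """Round-trip reader: returns (records, config_fingerprint).

    Each record is one (feature, candidate) with its tier, ambiguity set
    and per-platform evidence dictionaries.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# breathvoc-config"):
        raise InputError(f"{path}: missing config fingerprint line")
    fingerprint = lines[0].split()[-1]
    reader = csv.DictReader(lines[1:])
    if reader.fieldnames != _REPORT_COLUMNS:
        raise InputError(f"{path}: unexpected report columns")
    records: dict[tuple[str, str], dict] = {}
    for row in reader:
        if None in row.values():
            raise InputError(f"{path}: truncated report row")
        key = (row["feature_id"], row["candidate"])
        rec = records.setdefault(key, {
            "feature_id": row["feature_id"],
            "candidate": row["candidate"],
            "tier": Tier(row["tier"]),
            "ambiguity_set": [a for a in row["ambiguity_set"].split(";") if a],
            "evidence": [],
        })
        if row["platform"]:
            rec["evidence"].append({
                "platform": Platform(row["platform"]),
                "matched": row["matched"] == "True",
                "contradicts": row["contradicts"] == "True",
                "ri_match": None if row["ri_match"] == ""
                else row["ri_match"] == "True",
                "matched_ions": _ions_from_str(row["matched_ions"]),
            })
    return list(records.values()), fingerprint
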