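"""Declarative class->ion rule tables shared by the EI and PCI predictors.

Rules live in delimited text shipped as package data, one row per
(chemical class, carbon-range, transform). Keeping the tables as data —
rather than branching code — lets users extend or amend classes the same
way the underlying character-ion tables are published.

Transform tokens
----------------
``M``, ``M+H``, ``M-17`` ...  chem transform labels (offset from M);
``mz:43``                     a fixed fragment m/z, independent of M;
``series:acylium``            the CnH2n-1O2 acylium-type series evaluated
                              at the compound's own carbon count.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

from . import chem
from .errors import InputError, TransformDomainError, UnsupportedClassError
from .records import ChemClass, CompoundRecord, IntensityClass, IonPrediction, Platform

_COLUMNS = ["chem_class", "min_carbon", "max_carbon", "requires_flag",
            "transform", "intensity_class", "mechanism"]


@dataclass(frozen=True)
class RuleRow:
    chem_class: ChemClass
    transform: str
    intensity_class: IntensityClass
    mechanism: str
    min_carbon: Optional[int] = None
    max_carbon: Optional[int] = None
    requires_flag: Optional[str] = None  # e.g. "substituted_benzene"

    def applies_to(self, compound: CompoundRecord) -> bool:
        if compound.chem_class is not self.chem_class:
            return False
        c = compound.carbon_count or 0
        if self.min_carbon is not None and c < self.min_carbon:
            return False
        if self.max_carbon is not None and c > self.max_carbon:
            return False
        if self.requires_flag and not getattr(compound, self.requires_flag, False):
            return False
        return True

    def ion_mz(self, compound: CompoundRecord) -> int:
        if self.transform.startswith("mz:"):
            return int(self.transform[3:])
        if self.transform == "series:acylium":
            n = compound.carbon_count or 0
            counts = {"C": n, "H": 2 * n - 1, "O": 2}
            return chem.nominal_mass(counts)
        t = chem.IonTransform.from_label(self.transform)
        return chem.apply_transform(compound.molecular_mass, t)


def load_rules(source) -> list[RuleRow]:
    """Load a rule table from a path or an open text stream."""
    if hasattr(source, "read"):
        return _parse(source)
    with open(source, newline="") as fh:
        return _parse(fh)


def _parse(fh) -> list[RuleRow]:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None or list(reader.fieldnames) != _COLUMNS:
        raise InputError(
            f"rule table must have columns {_COLUMNS}, got {reader.fieldnames}"
        )
    rows = []
    for i, rec in enumerate(reader, start=2):
        if None in rec.values() or None in rec:
            raise InputError(f"rule table line {i}: wrong field count")
        rows.append(RuleRow(
            chem_class=ChemClass(rec["chem_class"]),
            min_carbon=int(rec["min_carbon"]) if rec["min_carbon"] else None,
            max_carbon=int(rec["max_carbon"]) if rec["max_carbon"] else None,
            requires_flag=rec["requires_flag"] or None,
            transform=rec["transform"],
            intensity_class=IntensityClass(rec["intensity_class"]),
            mechanism=rec["mechanism"],
        ))
    return rows


def dump_rules(rules: Iterable[RuleRow], path) -> None:
    """Serialise a rule table back to delimited text (round-trip safe)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in rules:
            writer.writerow([
                r.chem_class.value,
                "" if r.min_carbon is None else r.min_carbon,
                "" if r.max_carbon is None else r.max_carbon,
                r.requires_flag or "",
                r.transform,
                r.intensity_class.value,
                r.mechanism,
            ])


def packaged_rules(filename: str) -> list[RuleRow]:
    text = resources.files("breathvoc.data").joinpath(filename).read_text()
    return _parse(_io.StringIO(text))


def predict_from_rules(
    compound: CompoundRecord,
    rules: Iterable[RuleRow],
    platform: Platform,
) -> list[IonPrediction]:
    """Evaluate every applicable rule row for a compound on one platform."""
    rows = [r for r in rules if r.applies_to(compound)]
    if not any(r.chem_class is compound.chem_class for r in rules):
        cls = getattr(compound.chem_class, "value", compound.chem_class)
        raise UnsupportedClassError(
            f"no {platform.value} rules for class {cls!r}"
        )
    predictions: list[IonPrediction] = []
    seen: set[str] = set()
    for row in rows:
        try:
            mz = row.ion_mz(compound)
        except TransformDomainError as exc:
            raise TransformDomainError(
                f"{compound.name}: {exc} ({platform.value} rule "
                f"{row.transform!r})"
            ) from exc
        if row.transform in seen:  # one prediction per (platform, transform)
            continue
        seen.add(row.transform)
        predictions.append(IonPrediction(
            platform=platform,
            transform=row.transform,
            mz=mz,
            intensity_class=row.intensity_class,
            channel=row.mechanism,
        ))
    return predictions
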