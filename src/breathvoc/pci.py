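"""Water-reagent positive-chemical-ionisation diagnostic ions.

Water vapour infused as the CI reagent generates H3O+ (proton affinity
697 kJ/mol), a mild Bronsted acid: proton transfer to most oxygenated
VOCs yields a stable [M+H]+ base peak with little fragmentation. The
exceptions are the longer saturated aldehydes (>C4), where [M+H]+ drops
below 30% relative intensity and OH loss / inductive cleavage give
[M-17]+ and [M-73]+ as the intense ions, and alcohols, which undergo
hydride abstraction to [M-1]+ (with OH loss to [M-17]+ taking over as
base peak above C3).

Only the water reagent carries a parameterised rule set; methane
(PA 552) and methanol (PA 761, dimer/trimer-forming) are described as
reagent metadata only.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

from . import chem
from .errors import UnsupportedReagentError
from .records import (ChemClass, CompoundRecord, IntensityClass,
                      IonPrediction, Platform, ReagentSpec)
from .rules import RuleRow, load_rules, packaged_rules, predict_from_rules

__all__ = [
    "get_reagent", "known_reagents", "proton_transfer_favoured",
    "predict_pci_ions", "pci_rule_table", "load_rules",
]


@lru_cache(maxsize=1)
def known_reagents() -> dict[str, ReagentSpec]:
    text = resources.files("breathvoc.data").joinpath("reagents.csv").read_text()
    reader = csv.DictReader(text.splitlines())
    return {
        row["name"]: ReagentSpec(
            name=row["name"],
            proton_affinity=float(row["proton_affinity_kj_mol"]),
            forms_dimers=row["forms_dimers"].strip().lower() == "true",
        )
        for row in reader
    }


def get_reagent(name: str) -> ReagentSpec:
    try:
        return known_reagents()[name.lower()]
    except KeyError:
        raise UnsupportedReagentError(
            f"unknown CI reagent {name!r}; known: {sorted(known_reagents())}"
        ) from None


def proton_transfer_favoured(
    analyte_pa: float | None, reagent: ReagentSpec
) -> bool | None:
    """Is proton transfer from the reagent ion to the analyte exothermic?

    True iff the analyte's proton affinity strictly exceeds the reagent's.
    Returns ``None`` (indeterminate) when the analyte PA is unknown —
    never a silent default.
    """
    if analyte_pa is None:
        return None
    return analyte_pa > reagent.proton_affinity


@lru_cache(maxsize=1)
def pci_rule_table() -> tuple[RuleRow, ...]:
    return tuple(packaged_rules("pci_rules.csv"))


def predict_pci_ions(
    compound: CompoundRecord,
    reagent: ReagentSpec | str = "water",
    dimer_audit: bool = False,
    rules: tuple[RuleRow, ...] | None = None,
) -> list[IonPrediction]:
    """Predict water-PCI diagnostic ions for one compound.

    Parameters
    ----------
    reagent :
        Must be the water reagent — the only one with a published ion
        table; any other raises :class:`UnsupportedReagentError`.
    dimer_audit :
        When True, ketones additionally emit the proton-bound dimer
        [2M+H]+ flagged *absent*: no dimer formation is observed with
        water reagent, so an observed dimer peak argues against the
        water-PCI assignment (audit use only).
    """
    if isinstance(reagent, str):
        reagent = get_reagent(reagent)
    if reagent.name != "water":
        raise UnsupportedReagentError(
            f"no PCI ion rules for reagent {reagent.name!r}; only the water "
            "reagent is parameterised"
        )
    table = pci_rule_table() if rules is None else rules
    predictions = predict_from_rules(compound, table, Platform.PCI)
    if dimer_audit and compound.chem_class is ChemClass.KETONE:
        dimer = chem.IonTransform.from_label("2M+H")
        predictions.append(IonPrediction(
            platform=Platform.PCI,
            transform="2M+H",
            mz=chem.apply_transform(compound.molecular_mass, dimer),
            intensity_class=IntensityClass.ABSENT,
            channel="proton-bound-dimer (not formed with water reagent)",
        ))
    return predictions
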