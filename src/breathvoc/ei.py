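"""Characteristic 70 eV electron-ionisation fragments by chemical class.

Hard EI at 70 eV fragments oxygenated VOCs along class-characteristic
routes: aliphatic ketones alpha-cleave to the acylium ion at m/z 43;
saturated aldehydes (C4 and up) lose their molecular ion but show m/z 43
(alpha-cleavage) and m/z 44 (McLafferty rearrangement); the C3 aldehydes
propanal/propenal instead keep M+ with moderate HC=O loss to [M-29]+;
longer unsaturated aldehydes beta-cleave to m/z 41 (the printed value for
the ketene-type fragment); short acids keep M+ and lose OH to [M-17]+
while C4+ acids show the McLafferty enol at m/z 60 plus the CnH2n-1O2
acylium-type ion; primary alcohols give [M-18]+, [M-33]+, m/z 31 and
[M-1]+; aromatics keep a strong M+ and, when ring-substituted, the phenyl
fragment at m/z 77.

The rule set is a declarative table shipped as package data
(``data/ei_rules.csv``); ``load_rules``/``dump_rules`` round-trip it.
"""

from __future__ import annotations

from functools import lru_cache

from .records import CompoundRecord, IonPrediction, Platform
from .rules import RuleRow, load_rules, packaged_rules, predict_from_rules

__all__ = ["predict_ei_ions", "ei_rule_table", "load_rules"]


@lru_cache(maxsize=1)
def ei_rule_table() -> tuple[RuleRow, ...]:
    """The packaged EI rule table."""
    return tuple(packaged_rules("ei_rules.csv"))


def predict_ei_ions(
    compound: CompoundRecord,
    rules: tuple[RuleRow, ...] | None = None,
) -> list[IonPrediction]:
    """Predict the class-characteristic EI ions for one compound.

    No EI transform adds mass, so every predicted m/z is at most M; the
    proton-bound dimer is never predicted under EI.
    """
    table = ei_rule_table() if rules is None else rules
    return predict_from_rules(compound, table, Platform.EI)
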