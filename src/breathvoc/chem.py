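"""Elemental-formula arithmetic and ion-transform m/z computation.

Everything downstream (EI/PCI/SIFT rule tables, the annotation engine, the
synthetic generator) computes m/z through this module. Masses are nominal
(unit) masses: the instruments modelled here are unit-resolution
quadrupoles and every diagnostic ion is an integer m/z. All ions are
singly charged, so m/z equals the computed ion mass; the electron mass is
ignored (sub-mDa, irrelevant at unit resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pt_mass

from .errors import FormulaError, TransformDomainError

#: Integer mass of the most abundant isotope, per supported element.
ELEMENT_MASSES: dict[str, int] = {
    "C": 12,
    "H": 1,
    "N": 14,
    "O": 16,
    "S": 32,
    "P": 31,
    "F": 19,
    "Cl": 35,
    "Br": 79,
    "I": 127,
}

ElementCounts = dict[str, int]


def parse_formula(formula: str) -> ElementCounts:
    """Parse a Hill-style elemental formula into element counts.

    Parameters
    ----------
    formula :
        e.g. ``"C2H4O2"`` (acetic acid) or ``"C6H5"`` (phenyl fragment).

    Raises
    ------
    FormulaError
        Empty string, unknown element symbol, or zero total atoms.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty elemental formula")
    try:
        counts = dict(_pt_mass.Composition(formula=formula.strip()))
    except Exception as exc:  # pyteomics raises its own error type
        raise FormulaError(f"cannot parse formula {formula!r}: {exc}") from exc
    for symbol, n in counts.items():
        if symbol not in ELEMENT_MASSES:
            raise FormulaError(
                f"unknown element symbol {symbol!r} in formula {formula!r}"
            )
        if n < 0:
            raise FormulaError(f"negative count for {symbol!r} in {formula!r}")
    if sum(counts.values()) <= 0:
        raise FormulaError(f"formula {formula!r} contains no atoms")
    return counts


def format_formula(counts: ElementCounts) -> str:
    """Format element counts in Hill order (C, H, then alphabetical)."""
    order = [s for s in ("C", "H") if counts.get(s)]
    order += sorted(s for s in counts if s not in ("C", "H") and counts[s])
    return "".join(f"{s}{counts[s]}" if counts[s] != 1 else s for s in order)


def nominal_mass(counts: ElementCounts) -> int:
    """Nominal molecular mass in Da: sum of counts x integer isotope mass."""
    try:
        return sum(ELEMENT_MASSES[s] * n for s, n in counts.items())
    except KeyError as exc:
        raise FormulaError(f"unknown element symbol {exc.args[0]!r}") from exc


# label -> (scale, delta); hydrate adducts are parameterised separately.
_FIXED_TRANSFORMS: dict[str, tuple[int, int]] = {
    "M": (1, 0),
    "M+H": (1, 1),
    "M-H": (1, -1),
    "M-17": (1, -17),
    "M-18": (1, -18),
    "M-29": (1, -29),
    "M-33": (1, -33),
    "M-73": (1, -73),
    "M+NO": (1, 30),
    "2M+H": (2, 1),
}

WATER_MASS = 18  # H2O nominal


@dataclass(frozen=True)
class IonTransform:
    """A nominal-mass ion transform, e.g. ``[M+H]+`` or ``[M-17]+``.

    ``mz = scale * molecular_mass + delta`` for a singly charged ion.
    ``scale`` is 2 only for the proton-bound dimer ``[2M+H]+``.
    """

    label: str
    scale: int = 1
    delta: int = 0
    n_water: int = field(default=0, compare=True)

    @classmethod
    def from_label(cls, label: str, n: int | None = None) -> "IonTransform":
        """Build a transform from its bracketed-ion label.

        ``"M+H+nH2O"`` requires ``n`` in {1, 2} (hydrate adducts observed up
        to two waters); all other labels are fixed offsets.
        """
        if label == "M+H+nH2O":
            if n not in (1, 2):
                raise ValueError("hydrate adduct requires n in {1, 2}")
            return cls(label=f"M+H+{n}H2O", scale=1,
                       delta=1 + WATER_MASS * n, n_water=n)
        if label not in _FIXED_TRANSFORMS:
            raise ValueError(
                f"unknown transform label {label!r}; "
                f"known: {sorted(_FIXED_TRANSFORMS)} and 'M+H+nH2O'"
            )
        scale, delta = _FIXED_TRANSFORMS[label]
        return cls(label=label, scale=scale, delta=delta)


def apply_transform(molecular_mass: int, transform: IonTransform) -> int:
    """Apply an ion transform to a nominal molecular mass.

    Raises
    ------
    TransformDomainError
        If the resulting m/z would be non-positive (the rule does not
        apply to so light a molecule, e.g. ``M-73`` on propanal).
    """
    if molecular_mass <= 0:
        raise TransformDomainError(
            f"molecular mass must be positive, got {molecular_mass}"
        )
    mz = transform.scale * molecular_mass + transform.delta
    if mz <= 0:
        raise TransformDomainError(
            f"transform {transform.label} on M={molecular_mass} "
            f"yields non-positive m/z {mz}"
        )
    return mz
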