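"""SIFT-MS reaction-channel prediction and multi-ion-monitoring quantitation.

Selected-ion flow tube MS reacts breath VOCs with a selected precursor —
H3O+ (injected as the hydrate series m/z 19/37/55/73) or NO+ (m/z
30/48/66) — and identifies/quantifies analytes from known ion-molecule
reaction channels:

* H3O+: protonation to [M+H]+ for every class, with water-adduct series
  [M+H+nH2O]+ (n <= 2) for phenols, alcohols and acids; alcohols also
  dehydrate to [M+H-H2O]+.
* NO+: electron transfer to M+ (plus water adducts) for phenols;
  nitrosonium adduct [M+NO]+ (M+30) for ketones, unsaturated aldehydes
  and acids; hydride abstraction to [M-H]+ for saturated aldehydes.
  Acids additionally undergo dissociative ionisation — the fragment list
  is not predictable from class and must come from a kinetic library, so
  it is surfaced as a flag on the result.

Quantitation in multi-ion-monitoring (MIM) mode follows standard SIFT
kinetics: the analyte mixing ratio is proportional to the product-ion to
precursor-ion count-rate ratio divided by the rate coefficient k, the
reaction time t and the carrier-gas number density N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from . import chem
from .errors import UndefinedStatisticError, UnsupportedChannelError
from .records import (ChemClass, CompoundRecord, IntensityClass, IonPrediction,
                      KineticEntry, Platform, PrecursorIon)

__all__ = [
    "PRECURSORS", "precursor_series", "predict_sift_products",
    "SiftProducts", "quantify_mim",
]

#: The two precursors with their injected hydrate series and the typical
#: total count rates (used by the synthetic generator, never by quantitation).
PRECURSORS: dict[str, PrecursorIon] = {
    "H3O+": PrecursorIon("H3O+", (19, 37, 55, 73), 8e5),
    "NO+": PrecursorIon("NO+", (30, 48, 66), 4e5),
}

_PRECURSOR_PLATFORM = {"H3O+": Platform.SIFT_H3O, "NO+": Platform.SIFT_NO}


def precursor_series(name: str) -> list[int]:
    """The injected precursor hydrate series m/z (base ion + 18n)."""
    try:
        return list(PRECURSORS[name].hydrate_series_mz)
    except KeyError:
        raise UnsupportedChannelError(
            f"unknown precursor {name!r}; supported: {sorted(PRECURSORS)}"
        ) from None


@dataclass
class SiftProducts:
    """Predicted SIFT product ions plus channel metadata.

    Iterable over its :class:`IonPrediction` list so it can be passed
    anywhere a prediction list is expected. ``dissociative_ionisation``
    marks acid/NO+ chemistry whose fragment m/z must be read from a
    user-supplied kinetic library entry rather than predicted.
    """

    ions: list[IonPrediction]
    dissociative_ionisation: bool = False
    precursor: str = ""

    def __iter__(self) -> Iterator[IonPrediction]:
        return iter(self.ions)

    def __len__(self) -> int:
        return len(self.ions)


def _hydrate_adducts(platform: Platform, mass: int,
                     max_hydrates: int) -> list[IonPrediction]:
    out = []
    for n in range(1, max_hydrates + 1):
        t = chem.IonTransform.from_label("M+H+nH2O", n=n)
        out.append(IonPrediction(
            platform=platform, transform=t.label,
            mz=chem.apply_transform(mass, t),
            intensity_class=IntensityClass.MAJOR, channel="water-adduct"))
    return out


def predict_sift_products(
    compound: CompoundRecord,
    precursor: str | PrecursorIon = "H3O+",
    max_hydrates: int = 2,
) -> SiftProducts:
    """Predict product ions for one compound/precursor pair.

    Channels depend only on chemical class and precursor, never on
    intensities. ``max_hydrates`` caps the water-adduct series (two is
    what unit-resolution breath work resolves in practice).
    """
    name = precursor.name if isinstance(precursor, PrecursorIon) else precursor
    if name not in PRECURSORS:
        raise UnsupportedChannelError(
            f"unknown precursor {name!r}; supported: {sorted(PRECURSORS)}"
        )
    platform = _PRECURSOR_PLATFORM[name]
    cls = compound.chem_class
    mass = compound.molecular_mass
    mh = chem.apply_transform(mass, chem.IonTransform.from_label("M+H"))
    ions: list[IonPrediction] = []
    dissociative = False

    if name == "H3O+":
        ions.append(IonPrediction(platform, "M+H", mh,
                                  IntensityClass.BASE, "protonation"))
        if cls in (ChemClass.PHENOL, ChemClass.ALCOHOL_PRIMARY, ChemClass.ACID):
            ions.extend(_hydrate_adducts(platform, mass, max_hydrates))
        if cls is ChemClass.ALCOHOL_PRIMARY:
            t = chem.IonTransform.from_label("M-17")  # [M+H-H2O]+
            ions.append(IonPrediction(
                platform, "M-17", chem.apply_transform(mass, t),
                IntensityClass.MAJOR, "dehydration"))
    else:  # NO+
        if cls is ChemClass.PHENOL:
            ions.append(IonPrediction(
                platform, "M", mass, IntensityClass.BASE, "electron-transfer"))
            for n in range(1, max_hydrates + 1):
                t = chem.IonTransform(label=f"M+{18 * n}", delta=18 * n,
                                      n_water=n)
                ions.append(IonPrediction(
                    platform, t.label, chem.apply_transform(mass, t),
                    IntensityClass.MAJOR, "water-adduct"))
        elif cls in (ChemClass.KETONE, ChemClass.ALDEHYDE_UNSATURATED,
                     ChemClass.ACID):
            t = chem.IonTransform.from_label("M+NO")
            ions.append(IonPrediction(
                platform, "M+NO", chem.apply_transform(mass, t),
                IntensityClass.BASE, "nitrosonium-adduct"))
            if cls is ChemClass.ACID:
                dissociative = True
        elif cls is ChemClass.ALDEHYDE_SATURATED:
            t = chem.IonTransform.from_label("M-H")
            ions.append(IonPrediction(
                platform, "M-H", chem.apply_transform(mass, t),
                IntensityClass.BASE, "hydride-abstraction"))
        else:
            raise UnsupportedChannelError(
                f"no NO+ reaction channel for class {cls.value!r} "
                f"({compound.name})"
            )
    return SiftProducts(ions=ions, dissociative_ionisation=dissociative,
                        precursor=name)


def quantify_mim(
    product_counts: float,
    precursor_counts: float,
    kinetics: KineticEntry,
    reaction_time: float,
    number_density: float,
) -> float:
    """Analyte mixing ratio in ppbv from MIM count rates.

    concentration = I_product / (I_precursor * k * t * N), expressed as
    parts-per-billion of the carrier number density. Linear in
    ``product_counts``; averaging over the MIM acquisition window is the
    caller's concern.

    Parameters
    ----------
    product_counts, precursor_counts :
        Count rates (s^-1) summed over product ions and over the
        precursor hydrate series respectively.
    kinetics :
        Library entry supplying the rate coefficient k (cm^3 s^-1).
    reaction_time :
        Flow-tube reaction time t in seconds.
    number_density :
        Carrier-gas number density N in cm^-3.
    """
    if precursor_counts <= 0:
        raise UndefinedStatisticError(
            "precursor count rate must be positive; concentration undefined"
        )
    if product_counts < 0:
        raise UndefinedStatisticError("product count rate cannot be negative")
    if reaction_time <= 0 or number_density <= 0:
        raise UndefinedStatisticError(
            "reaction time and number density must be positive"
        )
    fraction = product_counts / (
        precursor_counts * kinetics.rate_coefficient
        * reaction_time * number_density
    )
    return fraction * 1e9
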