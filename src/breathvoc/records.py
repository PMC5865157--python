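"""Shared domain records: compounds, predictions, peaks, evidence, series."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import chem
from .errors import InputError


class Platform(str, enum.Enum):
    """One analytical platform as the annotation engine sees it.

    The two SIFT-MS precursors are modelled as independent platforms:
    each contributes its own evidence record to the consensus tier.
    """

    EI = "EI"
    PCI = "PCI"
    SIFT_H3O = "SIFT_H3O"
    SIFT_NO = "SIFT_NO"

    @property
    def has_chromatography(self) -> bool:
        return self in (Platform.EI, Platform.PCI)


class ChemClass(str, enum.Enum):
    KETONE = "ketone"
    ALDEHYDE_SATURATED = "aldehyde_saturated"
    ALDEHYDE_UNSATURATED = "aldehyde_unsaturated"
    ACID = "acid"
    ALCOHOL_PRIMARY = "alcohol_primary"
    PHENOL = "phenol"
    AROMATIC = "aromatic"


class IntensityClass(str, enum.Enum):
    """Three-level expected relative intensity, plus an explicit "absent"
    used for suppression notes (e.g. M+ missing in saturated-aldehyde EI,
    the ketone dimer absent under water-reagent PCI)."""

    BASE = "base"        # 100 %
    MAJOR = "major"      # 30-100 %
    MINOR = "minor"      # < 30 %
    ABSENT = "absent"


@dataclass
class CompoundRecord:
    """One library compound: identity, formula, class, reference RI.

    ``reference_ri`` is a Kovats-style retention index on the mid-polar
    624-phase column used for GC benchmarking; ``substituted_benzene``
    marks aromatics that shed a phenyl ``m/z 77`` fragment under EI.
    """

    name: str
    formula: chem.ElementCounts
    chem_class: ChemClass
    carbon_count: Optional[int] = None
    reference_ri: Optional[float] = None
    proton_affinity: Optional[float] = None  # kJ/mol
    substituted_benzene: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = chem.parse_formula(self.formula)
        self.chem_class = ChemClass(self.chem_class)
        formula_c = self.formula.get("C", 0)
        if self.carbon_count is None:
            self.carbon_count = formula_c
        elif self.carbon_count != formula_c:
            raise InputError(
                f"{self.name}: carbon_count {self.carbon_count} inconsistent "
                f"with formula ({formula_c} C atoms)"
            )
        if self.reference_ri is not None and self.reference_ri <= 0:
            raise InputError(f"{self.name}: reference RI must be positive")

    @property
    def molecular_mass(self) -> int:
        """Nominal molecular mass M in Da."""
        return chem.nominal_mass(self.formula)


@dataclass(frozen=True)
class IonPrediction:
    """One predicted diagnostic ion on one platform."""

    platform: Platform
    transform: str                 # transform label or fixed-m/z token
    mz: int
    intensity_class: IntensityClass
    channel: str = ""              # mechanism label, e.g. "alpha-cleavage"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise InputError(f"prediction m/z must be positive: {self.mz}")


@dataclass
class Peak:
    """One observed peak. GC rows carry a retention coordinate; SIFT rows
    carry none (no chromatographic separation)."""

    mz: float
    intensity: float
    retention_time: Optional[float] = None   # minutes
    retention_index: Optional[float] = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise InputError(f"negative intensity {self.intensity} at m/z {self.mz}")


@dataclass
class PeakTable:
    """Observed peaks for one sample on one platform."""

    platform: Platform
    peaks: list[Peak]
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        if self.platform.has_chromatography:
            for p in self.peaks:
                if p.retention_time is None and p.retention_index is None:
                    raise InputError(
                        f"{self.platform.value} peak at m/z {p.mz} lacks a "
                        "retention coordinate"
                    )

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class EvidenceRecord:
    """Per-platform outcome of matching predicted against observed ions.

    ``matched`` requires every base-class prediction to be observed and at
    least one base/major ion matched. ``contradicts`` flags a platform with
    a rich spectrum (>= the configured peak floor) in which none of the
    candidate's base/major ions appear.
    """

    platform: Platform
    matched: bool
    matched_ions: list[tuple[int, float, float]] = field(default_factory=list)
    ri_match: Optional[bool] = None          # None = not applicable
    library_score: Optional[int] = None
    contradicts: bool = False
    intensity_consistent: Optional[bool] = None


class Tier(str, enum.Enum):
    CONFIRMED = "confirmed"
    PROBABLE = "probable"
    TENTATIVE = "tentative"
    REJECTED = "rejected"


TIER_RANK = {Tier.CONFIRMED: 0, Tier.PROBABLE: 1, Tier.TENTATIVE: 2, Tier.REJECTED: 3}


@dataclass
class AnnotationResult:
    """Consensus outcome for one (feature, candidate) pair."""

    candidate: CompoundRecord
    evidence: list[EvidenceRecord]
    tier: Tier
    ambiguity_set: list[str] = field(default_factory=list)
    feature_id: str = ""

    @property
    def matched_platforms(self) -> int:
        return sum(1 for e in self.evidence if e.matched)

    @property
    def matched_ion_count(self) -> int:
        return sum(len(e.matched_ions) for e in self.evidence)


@dataclass
class CalibrationSeries:
    """Paired loading/response data for one compound on one platform.

    ``loading_to_ppbv`` converts a loading-axis quantity (mol, or vapour
    volume in mL from a permeation source) into a mixing ratio so LODs can
    be reported in ppbv.
    """

    compound: str
    platform: Platform
    points: list[tuple[float, float]]        # (loading, response)
    replicates: list[float] = field(default_factory=list)
    loading_to_ppbv: float = 1.0

    def __post_init__(self) -> None:
        if any(l <= 0 for l, _ in self.points):
            raise InputError("calibration loadings must be strictly positive")

    @property
    def loadings(self) -> list[float]:
        return [l for l, _ in self.points]

    @property
    def responses(self) -> list[float]:
        return [r for _, r in self.points]


@dataclass(frozen=True)
class PrecursorIon:
    """A SIFT-MS precursor with its hydrate series and typical count rate."""

    name: str
    hydrate_series_mz: tuple[int, ...]
    count_rate: float  # counts/s, summed over the hydrate series

    def __post_init__(self) -> None:
        diffs = {b - a for a, b in zip(self.hydrate_series_mz,
                                       self.hydrate_series_mz[1:])}
        if diffs and diffs != {chem.WATER_MASS}:
            raise InputError(
                f"{self.name}: hydrate series must increase in steps of 18"
            )


@dataclass
class KineticEntry:
    """User-supplied SIFT-MS kinetic-library entry."""

    compound: str
    precursor: str
    rate_coefficient: float                  # cm^3 s^-1
    products: list[tuple[int, float]]        # (m/z, branching fraction)

    def __post_init__(self) -> None:
        if self.rate_coefficient <= 0:
            raise InputError("rate coefficient must be positive")
        fractions = [f for _, f in self.products]
        if any(not 0 < f <= 1 for f in fractions) or \
                abs(sum(fractions) - 1.0) > 1e-9:
            raise InputError("branching fractions must lie in (0,1] and sum to 1")


@dataclass(frozen=True)
class ReagentSpec:
    """A CI reagent: proton affinity governs proton-transfer efficiency."""

    name: str
    proton_affinity: float  # kJ/mol
    forms_dimers: bool = False

    def __post_init__(self) -> None:
        if self.proton_affinity <= 0:
            raise InputError("proton affinity must be positive")
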