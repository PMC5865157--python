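"""Synthetic fixtures with the statistical structure the workflow assumes.

The generator emulates realistic measurement conditions: authentic-standard-style
compound mixtures spanning the oxygenated classes, per-platform peak
tables built from the rule predictions with multiplicative intensity
noise (default CV 9%, the replicate precision of the SIFT method), m/z
jitter at a tenth of a unit, retention-index jitter of 5 index units,
Poisson background decoy peaks uniform over the 20-250 m/z acquisition
window, permeation-style paired calibration series, and breath cohorts
whose class composition varies Dirichlet-style around the published
medians (ketones dominant at 77%).

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import ei as _ei, pci as _pci, sift as _sift
from .errors import UnsupportedChannelError
from .records import (ChemClass, CompoundRecord, CalibrationSeries,
                      IntensityClass, Peak, PeakTable, Platform)
from .annotate import PeakGroup

__all__ = [
    "SimulationConfig", "default_library", "simulate_platform_peaks",
    "simulate_peak_groups", "simulate_calibration_series",
    "simulate_replicates", "simulate_cohort",
]

_DEFAULT_MEDIANS = {"ketone": 77.0, "aldehyde": 10.0, "acid": 9.0,
                    "phenol": 3.0, "alcohol": 1.0}

#: Map rule-level classes onto the composition families reported per cohort.
CLASS_FAMILY = {
    ChemClass.KETONE: "ketone",
    ChemClass.ALDEHYDE_SATURATED: "aldehyde",
    ChemClass.ALDEHYDE_UNSATURATED: "aldehyde",
    ChemClass.ACID: "acid",
    ChemClass.ALCOHOL_PRIMARY: "alcohol",
    ChemClass.PHENOL: "phenol",
    ChemClass.AROMATIC: "aldehyde",  # benzaldehyde-type
}


class SimulationConfig(BaseModel):
    """Knobs of the generator; defaults are the documented measurement conditions."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    noise_cv: float = Field(0.09, ge=0, lt=1)       # 9% replicate RSD
    decoy_peak_rate: float = Field(5.0, ge=0)       # Poisson mean per feature
    mz_jitter_sd: float = Field(0.1, ge=0)
    ri_jitter_sd: float = Field(5.0, ge=0)          # index units
    base_intensity: float = Field(100.0, gt=0)
    major_band: tuple[float, float] = (30.0, 100.0)
    minor_band: tuple[float, float] = (1.0, 30.0)   # "< 30 %" class
    decoy_intensity_band: tuple[float, float] = (1.0, 40.0)
    mz_range: tuple[float, float] = (20.0, 250.0)   # acquisition window
    cohort_size: int = Field(40, ge=1)
    composition_medians: dict[str, float] = dict(_DEFAULT_MEDIANS)
    dirichlet_concentration: Optional[float] = Field(50.0, gt=0)
    sample_area_scale: float = Field(1e6, gt=0)

    @model_validator(mode="after")
    def _renormalise(self) -> "SimulationConfig":
        total = sum(self.composition_medians.values())
        if total <= 0:
            raise ValueError("composition medians must sum to a positive value")
        self.composition_medians = {
            k: 100.0 * v / total for k, v in self.composition_medians.items()
        }
        return self


def default_library() -> list[CompoundRecord]:
    """A 16-compound authentic-standard-style mixture.

    Retention indices are on the mid-polar 624-phase scale; the
    propanal/acetone and 2-/4-ethylphenol values are the benchmark pairs
    used to check isobar and isomer resolution, the rest are
    representative values for that column class.
    """
    rows = [
        ("propanal", "C3H6O", ChemClass.ALDEHYDE_SATURATED, 489.0, False),
        ("acetone", "C3H6O", ChemClass.KETONE, 498.0, False),
        ("2-propenal", "C3H4O", ChemClass.ALDEHYDE_UNSATURATED, 506.0, False),
        ("butanal", "C4H8O", ChemClass.ALDEHYDE_SATURATED, 596.0, False),
        ("2-butanone", "C4H8O", ChemClass.KETONE, 609.0, False),
        ("2-hexenal", "C6H10O", ChemClass.ALDEHYDE_UNSATURATED, 870.0, False),
        ("heptanal", "C7H14O", ChemClass.ALDEHYDE_SATURATED, 918.0, False),
        ("4-decanone", "C10H20O", ChemClass.KETONE, 1186.0, False),
        ("acetic acid", "C2H4O2", ChemClass.ACID, 627.0, False),
        ("butanoic acid", "C4H8O2", ChemClass.ACID, 821.0, False),
        ("hexanoic acid", "C6H12O2", ChemClass.ACID, 1012.0, False),
        ("1-propanol", "C3H8O", ChemClass.ALCOHOL_PRIMARY, 565.0, False),
        ("1-butanol", "C4H10O", ChemClass.ALCOHOL_PRIMARY, 674.0, False),
        ("phenol", "C6H6O", ChemClass.PHENOL, 995.0, False),
        ("2-ethylphenol", "C8H10O", ChemClass.PHENOL, 1286.0, True),
        ("4-ethylphenol", "C8H10O", ChemClass.PHENOL, 1323.0, True),
    ]
    return [
        CompoundRecord(name=n, formula=f, chem_class=c, reference_ri=ri,
                       substituted_benzene=flag)
        for n, f, c, ri, flag in rows
    ]


_PLATFORM_SALT = {Platform.EI: 1, Platform.PCI: 2,
                  Platform.SIFT_H3O: 3, Platform.SIFT_NO: 4}


def _rng(config: SimulationConfig, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *salt]))


def _predict(compound: CompoundRecord, platform: Platform):
    if platform is Platform.EI:
        return _ei.predict_ei_ions(compound)
    if platform is Platform.PCI:
        return _pci.predict_pci_ions(compound)
    precursor = "H3O+" if platform is Platform.SIFT_H3O else "NO+"
    return list(_sift.predict_sift_products(compound, precursor))


def _draw_intensity(rng, intensity_class: IntensityClass,
                    config: SimulationConfig) -> Optional[float]:
    if intensity_class is IntensityClass.ABSENT:
        return None
    if intensity_class is IntensityClass.BASE:
        nominal = config.base_intensity
    elif intensity_class is IntensityClass.MAJOR:
        nominal = rng.uniform(*config.major_band)
    else:
        nominal = rng.uniform(*config.minor_band)
    return float(max(nominal * (1.0 + rng.normal(0.0, config.noise_cv)), 1e-6))


def _compound_peaks(compound: CompoundRecord, platform: Platform,
                    config: SimulationConfig, rng) -> list[Peak]:
    try:
        predictions = _predict(compound, platform)
    except UnsupportedChannelError:
        return []
    ri = None
    if platform.has_chromatography and compound.reference_ri is not None:
        ri = float(compound.reference_ri + rng.normal(0.0, config.ri_jitter_sd))
    peaks = []
    for pred in predictions:
        intensity = _draw_intensity(rng, pred.intensity_class, config)
        if intensity is None:
            continue
        mz = float(pred.mz + rng.normal(0.0, config.mz_jitter_sd))
        peaks.append(Peak(mz=mz, intensity=intensity, retention_index=ri))
    for _ in range(rng.poisson(config.decoy_peak_rate)):
        peaks.append(Peak(
            mz=float(rng.uniform(*config.mz_range)),
            intensity=float(rng.uniform(*config.decoy_intensity_band)),
            retention_index=ri,
        ))
    return peaks


def simulate_platform_peaks(
    compounds: Sequence[CompoundRecord],
    platform: Platform | str,
    config: SimulationConfig,
    sample_id: str = "synthetic",
) -> PeakTable:
    """One platform's peak table for a compound mixture.

    Each compound contributes its predicted diagnostic ions, with
    intensities drawn from the band of their intensity class perturbed by
    ``noise_cv``, m/z jittered by ``mz_jitter_sd`` and (on GC platforms)
    a shared per-compound retention-index jitter; Poisson decoy peaks are
    appended uniformly over the acquisition window. Deterministic under a
    fixed seed.
    """
    platform = Platform(platform)
    peaks: list[Peak] = []
    for i, compound in enumerate(compounds):
        crng = _rng(config, _PLATFORM_SALT[platform], i)
        peaks.extend(_compound_peaks(compound, platform, config, crng))
    return PeakTable(platform=platform, peaks=peaks, sample_id=sample_id)


def simulate_peak_groups(
    compounds: Sequence[CompoundRecord],
    config: SimulationConfig,
    platforms: Sequence[Platform] = (Platform.EI, Platform.PCI,
                                     Platform.SIFT_H3O, Platform.SIFT_NO),
) -> list[tuple[str, PeakGroup]]:
    """Per-feature cross-platform peak groups with known ground truth.

    Returns ``(true_compound_name, PeakGroup)`` pairs — the idealised
    output of RI-based peak grouping, suitable for measuring annotation
    recovery. The group's ``observed_ri`` is the EI run's jittered value.
    """
    groups = []
    for i, compound in enumerate(compounds):
        tables = {}
        observed_ri = None
        for platform in platforms:
            crng = _rng(config, _PLATFORM_SALT[Platform(platform)], i)
            peaks = _compound_peaks(compound, Platform(platform), config, crng)
            if not peaks:
                continue
            if Platform(platform) is Platform.EI and peaks[0].retention_index is not None:
                observed_ri = peaks[0].retention_index
            tables[Platform(platform)] = PeakTable(
                platform=platform, peaks=peaks, sample_id=compound.name)
        groups.append((compound.name, PeakGroup(
            tables=tables, observed_ri=observed_ri, feature_id=f"F{i:03d}")))
    return groups


def simulate_calibration_series(
    true_slope: float,
    true_intercept: float,
    loadings: Sequence[float],
    config: SimulationConfig,
    compound: str = "synthetic",
    loading_to_ppbv: float = 1.0,
) -> tuple[CalibrationSeries, CalibrationSeries]:
    """Paired permeation-loading series on two platforms.

    Platform A responds proportionally to loading; platform B responds as
    ``true_slope * responseA_true + true_intercept``. Both carry
    multiplicative noise at ``noise_cv``; the loadings are shared, as
    with paired sorbent tubes loaded from one permeation source. With
    zero noise, ``fit_paired_response`` recovers the truth exactly.
    """
    if len(loadings) < 3 or any(l <= 0 for l in loadings):
        raise ValueError("need >= 3 strictly positive loadings")
    rng = _rng(config, 101)
    a_true = np.asarray(loadings, dtype=float)
    b_true = true_slope * a_true + true_intercept
    a_obs = a_true * (1.0 + rng.normal(0.0, config.noise_cv, a_true.size))
    b_obs = b_true * (1.0 + rng.normal(0.0, config.noise_cv, a_true.size))
    series_a = CalibrationSeries(
        compound=compound, platform=Platform.EI,
        points=list(zip(map(float, loadings), map(float, a_obs))),
        loading_to_ppbv=loading_to_ppbv)
    series_b = CalibrationSeries(
        compound=compound, platform=Platform.SIFT_H3O,
        points=list(zip(map(float, loadings), map(float, b_obs))),
        loading_to_ppbv=loading_to_ppbv)
    return series_a, series_b


def simulate_replicates(
    true_value: float, n: int, config: SimulationConfig, salt: int = 202
) -> list[float]:
    """Replicate responses at one loading with CV ``noise_cv``."""
    rng = _rng(config, salt)
    return [float(true_value * (1.0 + rng.normal(0.0, config.noise_cv)))
            for _ in range(n)]


def simulate_cohort(n_samples: int, config: SimulationConfig):
    """Per-sample annotated class areas for a synthetic breath cohort.

    Class fractions are drawn from a Dirichlet centred on the configured
    medians with the configured concentration (``None`` = no
    perturbation, every sample at the median profile); total area per
    sample is log-normal around ``sample_area_scale``.

    Returns a tidy DataFrame (``sample``, ``chem_class``, ``area``) ready
    for :func:`breathvoc.quantify.class_composition`.
    """
    import pandas as pd

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _rng(config, 303)
    classes = sorted(config.composition_medians)
    medians = np.array([config.composition_medians[c] for c in classes])
    rows = []
    for s in range(n_samples):
        if config.dirichlet_concentration is None:
            fractions = medians / medians.sum()
        else:
            alpha = config.dirichlet_concentration * medians / medians.sum()
            fractions = rng.dirichlet(alpha)
        total = config.sample_area_scale * rng.lognormal(0.0, 0.3)
        for cls, frac in zip(classes, fractions):
            rows.append({"sample": f"S{s:03d}", "chem_class": cls,
                         "area": float(total * frac)})
    return pd.DataFrame(rows)
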