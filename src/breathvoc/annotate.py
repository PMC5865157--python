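"""Cross-platform consensus annotation of breath-VOC features.

The route map: a GC feature whose spectral-library match is weak (match or
reverse-match score below 800) cannot be annotated from EI alone. For each
candidate compound the engine therefore predicts the diagnostic ions on
every available platform (EI, water-PCI, SIFT-MS with H3O+ and NO+),
matches them against the observed peak tables, compares the observed
retention index against the library value, and combines the evidence into
a confidence tier:

* confirmed — RI match and >= 2 MS platforms matched;
* probable  — >= 2 platforms matched without RI, or RI plus one platform;
* tentative — exactly one platform matched (or no evidence either way);
* rejected  — some platform with a rich spectrum contradicts every
  base/major ion of the candidate.

Retention coordinates are never compared across the EI and PCI runs
directly; cross-platform grouping of GC peaks uses the retention index
computed against the C5-C20 alkane ladder.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from . import ei as _ei, pci as _pci, sift as _sift
from .errors import ExtrapolationError, InputError, UnsupportedChannelError
from .records import (AnnotationResult, CompoundRecord, EvidenceRecord,
                      IntensityClass, IonPrediction, PeakTable, Platform,
                      Tier, TIER_RANK)

__all__ = [
    "AnnotationConfig", "PeakGroup", "compute_ri", "library_gate",
    "match_ions", "screen_candidates",
]


@dataclass(frozen=True)
class AnnotationConfig:
    """Tolerances and thresholds for evidence matching and tier assignment.

    ``mz_tolerance`` (+-0.3) reflects unit-resolution quadrupole mass
    accuracy; ``ri_tolerance`` (+-15 index units) absorbs run-to-run drift
    while still separating the closest printed isomer pair (RI 1286 vs
    1323). ``contradiction_min_peaks`` keeps sparse spectra from rejecting
    a candidate: absence of evidence on a near-empty spectrum is not
    contradiction.
    """

    mz_tolerance: float = 0.3
    ri_tolerance: float = 15.0
    gate_threshold: int = 800
    intensity_floor: float = 0.0
    contradiction_min_peaks: int = 3
    max_hydrates: int = 2
    reagent: str = "water"
    dimer_audit: bool = False


@dataclass
class PeakGroup:
    """Cross-platform peak sets attributed to one chromatographic feature.

    SIFT-MS has no chromatography; a SIFT table attached to a group is the
    caller's claim that those product ions are attributable to the
    feature. ``observed_ri`` is the feature's retention index on the
    alkane-ladder scale (None when no ladder was run).
    """

    tables: Mapping[Platform, PeakTable]
    observed_ri: Optional[float] = None
    feature_id: str = ""

    def __post_init__(self) -> None:
        self.tables = {Platform(k): v for k, v in self.tables.items()}
        for platform, table in self.tables.items():
            if table.platform is not platform:
                raise InputError(
                    f"peak table tagged {table.platform.value} filed under "
                    f"{platform.value}"
                )


def compute_ri(rt: float, alkane_ladder: Sequence[tuple[int, float]]) -> float:
    """Temperature-programmed (van den Dool/Kratz) retention index.

    ``RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n))`` for the alkanes
    n, n+1 bracketing the analyte. The ladder is the C5-C20 n-alkane mix;
    no silent extrapolation outside its span.
    """
    if len(alkane_ladder) < 2:
        raise InputError("alkane ladder needs at least two rungs")
    carbons = [c for c, _ in alkane_ladder]
    rts = [t for _, t in alkane_ladder]
    if sorted(carbons) != carbons or len(set(carbons)) != len(carbons):
        raise InputError("alkane ladder carbon numbers must strictly increase")
    if any(b <= a for a, b in zip(rts, rts[1:])):
        raise InputError("alkane ladder retention times must strictly increase")
    if not all(5 <= c <= 20 for c in carbons):
        raise InputError("alkane ladder spans C5-C20")
    if rt < rts[0] or rt > rts[-1]:
        raise ExtrapolationError(
            f"rt {rt} min outside ladder span [{rts[0]}, {rts[-1]}]"
        )
    i = min(bisect.bisect_right(rts, rt), len(rts) - 1) - 1
    n, rt_n = alkane_ladder[i]
    n1, rt_n1 = alkane_ladder[i + 1]
    return 100.0 * (n + (n1 - n) * (rt - rt_n) / (rt_n1 - rt_n))


def library_gate(match_score: int, reverse_match: int,
                 threshold: int = 800) -> bool:
    """Does a weak spectral-library hit require cross-platform evidence?

    True iff either score falls strictly below the threshold (scores of
    exactly 800 pass the gate). Scores live on the 0-1000 library scale.
    """
    for s in (match_score, reverse_match):
        if not 0 <= s <= 1000:
            raise InputError(f"library score {s} outside [0, 1000]")
    return min(match_score, reverse_match) < threshold


def match_ions(
    predictions: Sequence[IonPrediction],
    peaks: PeakTable,
    mz_tolerance: float = 0.3,
) -> EvidenceRecord:
    """Match one platform's predicted ions against its observed peaks.

    A prediction matches when an observed peak lies within
    ``mz_tolerance`` of its m/z. The record is ``matched`` when every
    base-class prediction is observed and at least one base/major ion
    matched. Whether the base prediction is also the most intense matched
    peak is recorded (``intensity_consistent``) but never required.
    """
    predictions = list(predictions)
    platforms = {p.platform for p in predictions}
    if platforms and platforms != {peaks.platform}:
        raise InputError(
            f"predictions for {sorted(p.value for p in platforms)} matched "
            f"against a {peaks.platform.value} peak table"
        )
    matched_ions: list[tuple[int, float, float]] = []
    matched_preds: list[IonPrediction] = []
    for pred in predictions:
        if pred.intensity_class is IntensityClass.ABSENT:
            continue
        best = None
        for peak in peaks.peaks:
            err = abs(peak.mz - pred.mz)
            if err <= mz_tolerance and (best is None or err < abs(best.mz - pred.mz)):
                best = peak
        if best is not None:
            matched_ions.append((pred.mz, best.mz, best.intensity))
            matched_preds.append(pred)

    scored = [p for p in predictions
              if p.intensity_class is not IntensityClass.ABSENT]
    base = [p for p in scored if p.intensity_class is IntensityClass.BASE]
    strong = [p for p in scored
              if p.intensity_class in (IntensityClass.BASE, IntensityClass.MAJOR)]
    base_ok = all(p in matched_preds for p in base)
    strong_hit = any(p in matched_preds for p in strong)
    matched = base_ok and strong_hit

    consistent: Optional[bool] = None
    if matched and base and matched_ions:
        top_obs = max(i for _, _, i in matched_ions)
        base_obs = [i for (mz, _, i), p in zip(matched_ions, matched_preds)
                    if p.intensity_class is IntensityClass.BASE]
        consistent = bool(base_obs) and max(base_obs) >= top_obs
    return EvidenceRecord(
        platform=peaks.platform,
        matched=matched,
        matched_ions=matched_ions,
        intensity_consistent=consistent,
    )


def _contradicts(evidence: EvidenceRecord, peaks: PeakTable,
                 config: AnnotationConfig) -> bool:
    rich = sum(1 for p in peaks.peaks if p.intensity > config.intensity_floor)
    return rich >= config.contradiction_min_peaks and not evidence.matched_ions


def _platform_predictions(
    candidate: CompoundRecord, platform: Platform, config: AnnotationConfig
) -> list[IonPrediction]:
    if platform is Platform.EI:
        return _ei.predict_ei_ions(candidate)
    if platform is Platform.PCI:
        return _pci.predict_pci_ions(candidate, reagent=config.reagent,
                                     dimer_audit=config.dimer_audit)
    precursor = "H3O+" if platform is Platform.SIFT_H3O else "NO+"
    return list(_sift.predict_sift_products(
        candidate, precursor, max_hydrates=config.max_hydrates))


def _sift_signature(candidate: CompoundRecord,
                    config: AnnotationConfig) -> frozenset[tuple[str, int]]:
    sig = set()
    for platform in (Platform.SIFT_H3O, Platform.SIFT_NO):
        try:
            for p in _platform_predictions(candidate, platform, config):
                sig.add((platform.value, p.mz))
        except UnsupportedChannelError:
            continue
    return frozenset(sig)


def screen_candidates(
    peak_group: PeakGroup,
    candidates: Sequence[CompoundRecord],
    config: AnnotationConfig = AnnotationConfig(),
) -> list[AnnotationResult]:
    """Rank candidate compounds against one feature's cross-platform peaks.

    For each candidate, evidence is gathered from every platform present
    in the group (platforms whose chemistry offers no channel for the
    candidate's class are skipped) plus the RI comparison. Results are
    sorted by tier, then matched-ion count, then name (deterministic under
    candidate permutation).

    Candidates that SIFT-MS alone cannot distinguish (identical product-
    ion sets, e.g. ethylphenol positional isomers) carry each other in
    ``ambiguity_set`` unless the retention index separates them.
    """
    if not candidates:
        raise InputError("candidate list is empty")
    if not peak_group.tables:
        raise InputError("peak group has no platform peak tables")

    results: list[AnnotationResult] = []
    signatures: dict[str, frozenset] = {}
    ri_matches: dict[str, Optional[bool]] = {}
    for cand in candidates:
        evidence: list[EvidenceRecord] = []
        contradiction = False
        for platform, table in sorted(peak_group.tables.items(),
                                      key=lambda kv: kv[0].value):
            try:
                preds = _platform_predictions(cand, platform, config)
            except UnsupportedChannelError:
                continue
            rec = match_ions(preds, table, config.mz_tolerance)
            rec.contradicts = _contradicts(rec, table, config)
            contradiction = contradiction or rec.contradicts
            evidence.append(rec)

        ri_match: Optional[bool] = None
        if peak_group.observed_ri is not None and cand.reference_ri is not None:
            ri_match = (abs(peak_group.observed_ri - cand.reference_ri)
                        <= config.ri_tolerance)
        for rec in evidence:
            rec.ri_match = ri_match if rec.platform.has_chromatography else None

        matched = sum(1 for e in evidence if e.matched)
        if contradiction:
            tier = Tier.REJECTED
        elif ri_match and matched >= 2:
            tier = Tier.CONFIRMED
        elif matched >= 2 or (ri_match and matched == 1):
            tier = Tier.PROBABLE
        else:
            tier = Tier.TENTATIVE

        signatures[cand.name] = _sift_signature(cand, config)
        ri_matches[cand.name] = ri_match
        results.append(AnnotationResult(
            candidate=cand, evidence=evidence, tier=tier,
            feature_id=peak_group.feature_id))

    # SIFT-indistinguishable isomers: same product-ion signature and not
    # separated by the retention index.
    for res in results:
        name = res.candidate.name
        sig = signatures[name]
        if not sig:
            continue
        twins = []
        for other in results:
            oname = other.candidate.name
            if oname == name or signatures[oname] != sig:
                continue
            separated = (ri_matches[name] is not None
                         and ri_matches[oname] is not None
                         and ri_matches[name] != ri_matches[oname])
            if not separated:
                twins.append(oname)
        res.ambiguity_set = sorted(twins)

    results.sort(key=lambda r: (TIER_RANK[r.tier], -r.matched_ion_count,
                                r.candidate.name))
    return results
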