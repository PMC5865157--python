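"""Annotate a GC feature whose spectral-library hit is too weak to trust.

Recreates the worked case of a chromatographic peak with library match
scores below 800: EI shows m/z 60 and 43, which a library search could
also call ammonium acetate (MW 77). Cross-platform evidence — the PCI
protonated ion at m/z 61 and the SIFT-MS H3O+ series 61/79/97 — settles
the identity as acetic acid and rejects the alternative.
"""

from breathvoc import (AnnotationConfig, ChemClass, CompoundRecord, Peak,
                       PeakGroup, PeakTable, Platform, library_gate,
                       screen_candidates)

needs_more = library_gate(match_score=720, reverse_match=790)
print(f"library scores 720/790 below 800 -> cross-platform workflow: "
      f"{needs_more}")

acetic = CompoundRecord("acetic acid", "C2H4O2", ChemClass.ACID,
                        reference_ri=627.0)
ammonium = CompoundRecord("ammonium acetate", "C2H7NO2", ChemClass.ACID)
print(f"candidate MWs: acetic acid {acetic.molecular_mass} Da, "
      f"ammonium acetate {ammonium.molecular_mass} Da")


def observed(platform, mzs, ri=None):
    return PeakTable(platform, [Peak(float(m), 50.0, retention_index=ri)
                                for m in mzs])


feature = PeakGroup(tables={
    Platform.EI: observed(Platform.EI, [60, 43], ri=627),
    Platform.PCI: observed(Platform.PCI, [61], ri=627),
    Platform.SIFT_H3O: observed(Platform.SIFT_H3O, [61, 79, 97]),
}, observed_ri=627.0, feature_id="RT15.59")

for result in screen_candidates(feature, [ammonium, acetic],
                                AnnotationConfig()):
    flags = ", ".join(f"{e.platform.value}:"
                      f"{'match' if e.matched else 'no-match'}"
                      + ("(contradicts)" if e.contradicts else "")
                      for e in result.evidence)
    print(f"{result.candidate.name:18} tier={result.tier.value:9} [{flags}]")
print("Ammonium acetate's predicted [M+H]+ 78 and H3O+ adducts are absent "
      "from the soft-ionisation spectra, so it is screened out.")
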