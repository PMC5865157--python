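# breathvoc

Cross-platform annotation of oxygenated volatile organic compounds (VOCs)
in exhaled breath.

Disease breathomics screens exhaled breath for volatile biomarkers, but a
single GC-MS run with a weak spectral-library hit (match/reverse-match
score below 800 on the 0–1000 scale) cannot support a confident compound
identity. `breathvoc` implements the orthogonal, multi-platform strategy
used for that problem: predict the class-characteristic diagnostic ions a
compound must show on each of three platforms —

* **GC-EI-MS** (70 eV electron ionisation): α-cleavage acylium *m/z* 43 for
  ketones, McLafferty ions (*m/z* 44 aldehydes, *m/z* 60 acids), the
  CₙH₂ₙ₋₁O₂⁺ acylium series for longer acids, [M−H₂O]⁺/[M−33]⁺/*m/z* 31 for
  primary alcohols, M⁺ and phenyl *m/z* 77 for aromatics;
* **GC-PCI-MS with water reagent** (proton affinity 697 kJ mol⁻¹): [M+H]⁺
  base peaks for most classes, with [M−17]⁺/[M−73]⁺ taking over for >C4
  saturated aldehydes and [M−H]⁺/[M−17]⁺ for alcohols;
* **SIFT-MS** with H₃O⁺ (*m/z* 19/37/55/73) or NO⁺ (*m/z* 30/48/66)
  precursors: protonation and water-adduct series [M+H+nH₂O]⁺, electron
  transfer, nitrosonium adducts [M+NO]⁺ (M+30) and hydride abstraction
  [M−H]⁺, by class —

then match those predictions against observed peak tables and the Kovats
retention index (RI, computed on the C5–C20 n-alkane ladder by
RI = 100·(n + (rt − rtₙ)/(rtₙ₊₁ − rtₙ))), and combine the evidence into a
consensus tier per candidate:

| tier | requirement |
|---|---|
| confirmed | RI match **and** ≥ 2 MS platforms matched |
| probable | ≥ 2 platforms (no RI), or RI + 1 platform |
| tentative | exactly 1 platform matched |
| rejected | a rich spectrum contradicts every base/major ion |

The package also covers the surrounding quantitative workflow:
paired-response regression between platforms, relative standard
deviation, ICH-style detection limits (LOD = 3.3 σ_blank/slope, in ppbv),
per-cohort class-composition profiles, SIFT multi-ion-monitoring
quantitation from kinetic-library rate coefficients, and a synthetic-data
generator that emulates all of the input tables.

## Worked example

Screening the classic ambiguous feature — EI shows *m/z* 60 and 43 with a
weak library hit that could also be called ammonium acetate (MW 77 Da):

```python
from breathvoc import (ChemClass, CompoundRecord, Peak, PeakGroup,
                       PeakTable, Platform, screen_candidates)

acetic = CompoundRecord("acetic acid", "C2H4O2", ChemClass.ACID,
                        reference_ri=627.0)
ammonium = CompoundRecord("ammonium acetate", "C2H7NO2", ChemClass.ACID)

obs = lambda plat, mzs, ri=None: PeakTable(
    plat, [Peak(float(m), 50.0, retention_index=ri) for m in mzs])
feature = PeakGroup(tables={
    Platform.EI: obs(Platform.EI, [60, 43], ri=627),
    Platform.PCI: obs(Platform.PCI, [61], ri=627),
    Platform.SIFT_H3O: obs(Platform.SIFT_H3O, [61, 79, 97]),
}, observed_ri=627.0)

for r in screen_candidates(feature, [ammonium, acetic]):
    print(r.candidate.name, r.tier.value,
          [(e.platform.value, e.matched) for e in r.evidence])
```

prints

```
acetic acid confirmed [('EI', True), ('PCI', True), ('SIFT_H3O', True)]
ammonium acetate rejected [('EI', True), ('PCI', False), ('SIFT_H3O', False)]
```

Acetic acid matches its predicted ions on all three platforms plus the
retention index, so it is tier-confirmed; ammonium acetate's predicted
[M+H]⁺ at *m/z* 78 and its H₃O⁺ adduct series are absent from the
soft-ionisation spectra, which rejects it — even though its [M−17]⁺ at 60
coincidentally matches the EI spectrum.

The `examples/` directory holds one short script per capability
(diagnostic-ion prediction, weak-hit annotation, platform
intercomparison, simulate-and-recover); each prints its numbers with a
line on what they mean. A thin CLI mirrors the workflow stages:

```sh
breathvoc simulate peaks --seed 4 --out sim/
breathvoc annotate --library sim/library.csv --ei sim/peaks_EI.csv \
    --pci sim/peaks_PCI.csv --sift-h3o sim/peaks_SIFT_H3O.csv --out report.csv
breathvoc compare --series-a a.csv --series-b b.csv
```

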