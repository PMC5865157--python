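"""Predict per-platform diagnostic ions for a handful of breath VOCs.

Each chemical class fragments (EI), protonates or dissociates (water-PCI)
and reacts with H3O+/NO+ (SIFT-MS) along characteristic routes; the
printed m/z values are the ions an analyst would look for to claim the
compound on that platform.
"""

from breathvoc import (ChemClass, CompoundRecord, predict_ei_ions,
                       predict_pci_ions, predict_sift_products)

compounds = [
    CompoundRecord("propanal", "C3H6O", ChemClass.ALDEHYDE_SATURATED),
    CompoundRecord("heptanal", "C7H14O", ChemClass.ALDEHYDE_SATURATED),
    CompoundRecord("acetic acid", "C2H4O2", ChemClass.ACID),
    CompoundRecord("1-butanol", "C4H10O", ChemClass.ALCOHOL_PRIMARY),
    CompoundRecord("phenol", "C6H6O", ChemClass.PHENOL),
]

for compound in compounds:
    print(f"\n{compound.name} (M = {compound.molecular_mass} Da,"
          f" {compound.chem_class.value})")
    ei = ", ".join(f"{p.mz} ({p.channel}, {p.intensity_class.value})"
                   for p in predict_ei_ions(compound))
    print(f"  EI 70 eV : {ei}")
    pci = ", ".join(f"{p.mz} ({p.channel}, {p.intensity_class.value})"
                    for p in predict_pci_ions(compound, reagent="water"))
    print(f"  water-PCI: {pci}")
    for precursor in ("H3O+", "NO+"):
        try:
            products = predict_sift_products(compound, precursor)
        except Exception as exc:
            print(f"  SIFT {precursor:4}: no channel ({exc})")
            continue
        ions = ", ".join(f"{p.mz} ({p.channel})" for p in products)
        extra = " + dissociative fragments from kinetic library" \
            if products.dissociative_ionisation else ""
        print(f"  SIFT {precursor:4}: {ions}{extra}")
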