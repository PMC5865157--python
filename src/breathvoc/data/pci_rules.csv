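chem_class,min_carbon,max_carbon,requires_flag,transform,intensity_class,mechanism
phenol,,,,M+H,base,proton-transfer
ketone,,,,M+H,base,proton-transfer
aldehyde_unsaturated,,,,M+H,base,proton-transfer
acid,,,,M+H,base,proton-transfer
aromatic,,,,M+H,base,proton-transfer
aldehyde_saturated,5,,,M-17,base,OH-loss
aldehyde_saturated,5,,,M-73,major,inductive-cleavage
aldehyde_saturated,5,,,M+H,minor,proton-transfer
aldehyde_saturated,,4,,M+H,base,proton-transfer
alcohol_primary,,3,,M-H,base,hydride-abstraction
alcohol_primary,4,,,M-17,base,OH-loss
alcohol_primary,4,,,M-H,major,hydride-abstraction
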