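chem_class,min_carbon,max_carbon,requires_flag,transform,intensity_class,mechanism
ketone,,,,mz:43,base,alpha-cleavage
ketone,,,,M,minor,molecular-ion
aldehyde_saturated,4,,,mz:43,major,alpha-cleavage
aldehyde_saturated,4,,,mz:44,major,McLafferty
aldehyde_saturated,4,,,M,absent,molecular-ion-suppressed
aldehyde_saturated,,3,,M,major,molecular-ion
aldehyde_saturated,,3,,M-29,major,HCO-loss
aldehyde_unsaturated,,3,,M,major,molecular-ion
aldehyde_unsaturated,,3,,M-29,major,HCO-loss
aldehyde_unsaturated,4,,,mz:41,base,beta-cleavage
acid,,3,,M,major,molecular-ion
acid,,3,,M-17,major,OH-loss
acid,4,,,mz:60,base,McLafferty
acid,4,,,series:acylium,major,acylium-series
alcohol_primary,,,,M-18,major,water-loss
alcohol_primary,,,,M-33,major,water-plus-methyl-loss
alcohol_primary,,,,mz:31,major,oxocarbenium
alcohol_primary,,,,M-H,major,alpha-hydride-loss
phenol,,,,M,base,molecular-ion
phenol,,,substituted_benzene,mz:77,major,phenyl
aromatic,,,,M,base,molecular-ion
aromatic,,,substituted_benzene,mz:77,major,phenyl
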