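name,proton_affinity_kj_mol,forms_dimers
water,697,false
methane,552,false
methanol,761,true
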