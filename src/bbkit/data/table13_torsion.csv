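ligand_id,phi_solid_deg,phi_complex_deg
Ara-C,28.83,36.41
2'-deoxycytidine 1P60,,49.63
2'-deoxycytidine 1P61,,41.42
2'-deoxycytidine,44.14,47.99
cytidine,18.30,46.52
5-azacytidine,,48.48
3'-deoxycytidine,35.64,50.29
Zalcitabine,23.29,66.43
3'-dehydro-dideoxycytidine,,48.05
Gemcitabine 1P62,,47.59
Gemcitabine,,38.30
Decitabine,18.13,18.13
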