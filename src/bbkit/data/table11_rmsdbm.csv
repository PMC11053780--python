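series,ligand,value
native_vs_ligand,Ara-C,0.878
native_vs_ligand,2'-deoxycytidine,1.378
native_vs_ligand,cytidine,1.739
native_vs_ligand,5-azacytidine,1.622
native_vs_ligand,3'-deoxycytidine,1.717
native_vs_ligand,Zalcitabine,1.666
native_vs_ligand,3'-dehydro-dideoxycytidine,1.738
native_vs_ligand,Gemcitabine,1.259
native_vs_ligand,Decitabine,1.230
ligand_vs_own_native,Ara-C,0.878
ligand_vs_own_native,2'-deoxycytidine 1P60,0.913
ligand_vs_own_native,2'-deoxycytidine 1P61,1.230
ligand_vs_own_native,Gemcitabine 1P62,1.786
original_vs_redocked,Ara-C,0.878
original_vs_redocked,2'-deoxycytidine 1P60,1.933
original_vs_redocked,2'-deoxycytidine 1P61,1.660
original_vs_redocked,Gemcitabine 1P62,1.354
redocked_pair,2'-deoxycytidine 1P60,0.989
redocked_pair,2'-deoxycytidine 1P61,0.989
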