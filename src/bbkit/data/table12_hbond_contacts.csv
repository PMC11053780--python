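residue,Ara-C,2'-deoxycytidine,cytidine,5-azacytidine,3'-deoxycytidine,Zalcitabine,3'-dehydro-dideoxycytidine,Gemcitabine,Decitabine
Phe137,pi-pi/hydrophobic,pi-pi/hydrophobic,pi-pi/hydrophobic,pi-pi/hydrophobic,pi-pi/hydrophobic,pi-pi/hydrophobic,pi-pi/hydrophobic,pi-pi/hydrophobic,pi-pi/hydrophobic
Gln97,-NH2 -N=,-NH2 -N=,-NH2 -N=,-N=,-NH2,-NH2 -N=,-NH2 -N=,-NH2 -N=,-NH2 -N=
Glu53,CH2OH,CH2OH,CH2OH,CH2OH,CH2OH,CH2OH,CH2OH,CH2OH,CH2OH
Phe96,hydrophobic,hydrophobic,hydrophobic,hydrophobic,hydrophobic,hydrophobic,hydrophobic,hydrophobic,hydrophobic
Arg128,OH CH2OH,CH2OH,,,,,,CH2OH,CH2OH
Trp58,,,,,,,,,
Asp133,NH2,NH2,NH2,NH2,NH2,NH2,NH2,NH2,NH2
Ile30,,,,,,,,,
Tyr86,OH,OH,OH,OH,OH,,OH,OH,OH
Glu197,OH,OH,OH,OH,,,,OH,
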