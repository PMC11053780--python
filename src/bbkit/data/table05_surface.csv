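structure_id,S_C,S_H,S_N,S_O
ara_c,6.95,67.5,7.05,18.4
cytidine_alpha,6.25,69.3,6.8,17.65
cytidine_beta,6.20,68.25,5.80,17.75
deoxycytidine_2p_alpha,5.9,71.27,7,15.77
deoxycytidine_2p_beta,4.5,70.7,6.8,17.9
deoxycytidine_3p,7,67.8,7.6,17.8
zalcitabine,6.7,73.5,7.3,12.5
decitabine,4.95,67.25,12.2,15.7
cytosine,12.3,59.25,13.8,14.65
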