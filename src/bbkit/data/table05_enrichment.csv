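structure_id,pair,value
ara_c,CC,0
ara_c,CH,0.94
ara_c,HH,0.91
ara_c,CN,1.02
ara_c,NH,1.26
ara_c,NN,0
ara_c,CO,1.60
ara_c,OH,1.26
ara_c,NO,0.42
ara_c,OO,0.06
cytidine_alpha,CC,7.17
cytidine_alpha,CH,0.38
cytidine_alpha,HH,1.01
cytidine_alpha,CN,2.00
cytidine_alpha,NH,0.92
cytidine_alpha,NN,1.51
cytidine_alpha,CO,0.86
cytidine_alpha,OH,1.19
cytidine_alpha,NO,0.75
cytidine_alpha,OO,0.39
cytidine_beta,CC,0.26
cytidine_beta,CH,0.93
cytidine_beta,HH,0.96
cytidine_beta,CN,0.71
cytidine_beta,NH,1.09
cytidine_beta,NN,0.87
cytidine_beta,CO,1.68
cytidine_beta,OH,1.19
cytidine_beta,NO,0.87
cytidine_beta,OO,0.13
deoxycytidine_2p_alpha,CC,2.87
deoxycytidine_2p_alpha,CH,1.13
deoxycytidine_2p_alpha,HH,0.87
deoxycytidine_2p_alpha,CN,0.36
deoxycytidine_2p_alpha,NH,1.34
deoxycytidine_2p_alpha,NN,0.00
deoxycytidine_2p_alpha,CO,0.00
deoxycytidine_2p_alpha,OH,1.39
deoxycytidine_2p_alpha,NO,0.14
deoxycytidine_2p_alpha,OO,0.00
deoxycytidine_2p_beta,CC,0.00
deoxycytidine_2p_beta,CH,1.23
deoxycytidine_2p_beta,HH,0.87
deoxycytidine_2p_beta,CN,0.00
deoxycytidine_2p_beta,NH,1.35
deoxycytidine_2p_beta,NN,0.00
deoxycytidine_2p_beta,CO,0.74
deoxycytidine_2p_beta,OH,1.34
deoxycytidine_2p_beta,NO,0.25
deoxycytidine_2p_beta,OO,0.03
deoxycytidine_3p,CC,3.47
deoxycytidine_3p,CH,0.94
deoxycytidine_3p,HH,0.98
deoxycytidine_3p,CN,1.14
deoxycytidine_3p,NH,1.00
deoxycytidine_3p,NN,0.00
deoxycytidine_3p,CO,0.20
deoxycytidine_3p,OH,1.08
deoxycytidine_3p,NO,1.38
deoxycytidine_3p,OO,0.85
zalcitabine,CC,0.00
zalcitabine,CH,1.28
zalcitabine,HH,0.91
zalcitabine,CN,0.00
zalcitabine,NH,1.29
zalcitabine,NN,0.44
zalcitabine,CO,0.48
zalcitabine,OH,1.23
zalcitabine,NO,0.26
zalcitabine,OO,0.00
decitabine,CC,0.00
decitabine,CH,0.92
decitabine,HH,0.95
decitabine,CN,1.32
decitabine,NH,1.08
decitabine,NN,0.60
decitabine,CO,1.42
decitabine,OH,1.18
decitabine,NO,0.84
decitabine,OO,0.20
cytosine,CC,2.45
cytosine,CH,0.65
cytosine,HH,0.92
cytosine,CN,1.47
cytosine,NH,1.25
cytosine,NN,0.05
cytosine,CO,0.75
cytosine,OH,1.39
cytosine,NO,0.49
cytosine,OO,0.09
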