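ligand_id,e_homo,e_lumo,gap,chi,hardness,omega,softness,omega_plus_col,omega_minus_col,net_electrophilicity,r_plus,r_minus
Ara-C 15PZ,-7.490,0.143,7.633,3.673,3.816,1.768,0.262,4.082,0.408,4.490,1.000,1.000
Ara-C,-7.321,0.204,7.525,3.559,3.762,1.683,0.266,3.933,0.374,4.307,0.964,0.916
cytidine,-7.707,-0.748,6.959,4.228,3.479,2.568,0.287,5.117,0.890,6.007,1.254,2.179
2'-deoxycytidine,-7.308,0.151,7.458,3.578,3.729,1.717,0.268,3.972,0.394,4.366,0.973,0.965
3'-deoxycytidine,-7.709,-0.208,7.501,3.958,3.750,2.089,0.267,4.537,0.579,5.115,1.112,1.417
Zalcitabine,-7.549,0.079,7.628,3.735,3.814,1.828,0.262,4.173,0.438,4.611,1.022,1.072
5-azacytidine,-8.406,-0.488,7.917,4.447,3.959,2.498,0.253,5.216,0.769,5.985,1.278,1.884
Gemcitabine,-7.122,0.107,7.229,3.507,3.614,1.702,0.277,3.907,0.400,4.307,0.957,0.979
Decitabine,-7.983,0.187,8.170,3.898,4.085,1.859,0.245,4.319,0.421,4.740,1.058,1.032
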