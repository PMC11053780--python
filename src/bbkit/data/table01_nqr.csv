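compound,site,nu_plus,nu_minus,nu_zero,cqcc_printed,eta_printed,assignment,derived_field
Ara-C,N(1),2.555,2.055,0.500,3.073,0.325,-NH2,
Ara-C,N(2),2.890,1.800,1.090,3.147,0.712,-N=,nu_zero
Ara-C,N(3),2.530,2.315,0.215,3.230,0.133,>N-sugar,
cytidine,N(1),2.476,1.974,0.502,2.967,0.338,-NH2,
cytidine,N(2),2.683,1.463,1.220,2.769,0.883,-N=,
cytidine,N(3),2.356,,,,,>N-sugar,
5-azacytidine,N(1),2.140,1.420,0.715,2.373,0.603,-NH2,
5-azacytidine,N(2),2.740,2.120,0.620,3.240,0.383,-N(3)=,nu_minus
5-azacytidine,N(3),2.720,2.100,0.620,3.243,0.386,-N(5)=,nu_minus
5-azacytidine,N(4),2.200,,,,,>N-sugar,
cytosine,N(1),2.492,1.922,0.570,2.491,0.388,-NH2,
cytosine,N(2),2.723,1.570,1.153,2.862,0.806,-N=,
cytosine,N(3),2.028,1.219,0.801,2.165,0.740,>NH,
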