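structure,variant,site,nu_plus,nu_minus,nu_zero,cqcc_signed,eta,s,r_squared
Ara-C,hydrogens optimized,-NH2,2.658,2.175,0.483,-3.222,0.30,0.065,0.997
Ara-C,hydrogens optimized,-N=,2.835,1.970,0.865,-3.203,0.54,,
Ara-C,hydrogens optimized,>N-sugar,2.565,2.289,0.275,-3.236,0.17,,
Ara-C,X-ray hydrogens,-NH2,2.568,1.677,0.891,-2.83,0.63,,
Ara-C,X-ray hydrogens,-N=,2.844,2.031,0.813,-3.25,0.50,0.235,0.940
Ara-C,X-ray hydrogens,>N-sugar,2.519,2.218,0.300,-3.158,0.19,,
beta-cytidine,hydrogens optimized,-NH2,2.566,2.276,0.291,-3.228,0.18,0.158,0.974
beta-cytidine,hydrogens optimized,-N=,2.699,1.619,1.080,-2.879,0.75,,
beta-cytidine,hydrogens optimized,>N-sugar,2.406,2.221,0.185,-3.085,0.12,,
Zalcitabine,hydrogens optimized,-NH2,2.525,2.151,0.374,-3.117,0.24,,
Zalcitabine,hydrogens optimized,-N=,2.673,1.627,1.046,-2.867,0.73,,
Zalcitabine,hydrogens optimized,>N-sugar,2.317,2.153,0.164,-2.980,0.11,,
cytosine,hydrogens optimized,-NH2,2.732,2.005,0.726,-3.158,0.46,0.175,0.955
cytosine,hydrogens optimized,-N=,2.643,1.643,1.000,-2.857,0.70,,
cytosine,hydrogens optimized,>NH,2.243,1.537,0.706,-2.520,0.56,,
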