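compound,bond,r_ab_A,angle_deg,e_electrostatic,e_polarization,e_dispersion,e_repulsion,e_total,moiety,intramolecular
Ara-C,OH...O,2.650,155.45,,,,,,Ry,1
Ara-C,CH...O,3.685,157.20,,,,,,Ry,1
Ara-C,NH...O,2.983,163.70,-32.7,-8.9,-21.1,28.1,-42.3,-NH2,0
Ara-C,NH...O,3.048,145.73,-16.3,-10.2,-27,29,-30.4,-NH2,0
Ara-C,OH...O,3.003,159.64,-33.4,-9.3,-23.4,30.5,-43.7,Ry,0
Ara-C,OH...O,2.720,171.72,-74.7,-25.5,-20.5,66.6,-74.5,Ry,0
Ara-C,CH...N,3.652,159.76,,,,,,-N=,0
cytidine_alpha,NH...O,2.946,171.58,-28.1,-6.6,-12.6,29.2,-27.5,-NH2,0
cytidine_alpha,NH...O,3.183,144.97,-30.4,-8.7,-15,18.7,-40.0,-NH2,0
cytidine_alpha,OH...O,2.674,151.65,-45.3,-9.3,-13.1,49.6,-35.6,Ry,0
cytidine_alpha,OH...N,2.752,168.40,-132.5,-38.9,-57,169.4,-113.9,-N=,0
cytidine_beta,NH...O,2.946,147.84,-54.4,-10.5,-15.3,43.4,-51.8,-NH2,0
cytidine_beta,OH...N,2.860,174.31,-114.8,-35.9,-24.6,115.0,-98.3,-N=,0
cytidine_beta,CH...O,3.346,152.44,1.9,-2.9,-11.2,12.2,-2.4,C(5)/OH(Ry),0
deoxycytidine_2p_alpha,OH...O,2.716,150.58,-92.2,-27,-26.6,89,-86.4,=O,0
deoxycytidine_2p_alpha,NH...O,2.949,167.22,-33.3,-8.9,-31.8,47.7,-40.0,-NH2,0
deoxycytidine_2p_beta,NH...O,2.967,141.59,-83.2,-20.3,-17.2,64.3,-78.3,-NH2,0
deoxycytidine_2p_beta,NH...O,3.009,153.35,-49.7,-15.3,-23.8,52.8,-52.0,-NH2,0
deoxycytidine_3p,OH...HO,2.820,117.07,-5.0,-17.3,-14.3,58.2,5.5,Ry,0
deoxycytidine_3p,NH...O,2.858,143.47,-39.8,-11.2,-14.2,35.6,-40.7,-NH2,0
deoxycytidine_3p,NH...O,3.503,144.35,-0.1,-10,-16.9,29.5,-4,-NH2,0
zalcitabine,NH...O,2.977,166.77,-37,-11.6,-13.7,30,-41.2,-NH2,0
zalcitabine,NH...O,3.268,159.33,-24.8,-4.8,-15.7,15.1,-34.2,-NH2,0
zalcitabine,OH...N,2.774,168.64,-73.5,-23.3,-26.4,75.3,-62.8,-N=,0
decitabine,NH...N,2.873,166.70,-89.2,-22.9,-18.7,104.8,-62.9,-NH2,0
decitabine,OH...O,2.678,170.94,-52.5,-15.8,-16.2,60.0,-44.2,=O,0
decitabine,OH...O,2.742,153.01,-38.4,-9.1,-23.2,51.6,-35.7,Ry,0
cytosine,NH...O,3.022,166.42,-101.4,-27,-17.5,84.8,-90.1,-NH2,0
cytosine,NH...N,2.791,144.49,-41.2,-10.8,-5.6,23.5,-42.9,-N=,0
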