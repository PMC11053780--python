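residue,Ara-C 15PZ,Ara-C,2'-deoxycytidine 1P60,2'-deoxycytidine 1P61,2'-deoxycytidine,cytidine,5-azacytidine,3'-deoxycytidine,Zalcitabine,3'-dehydro-dideoxycytidine,Gemcitabine 1P62,Gemcitabine,Decitabine
Phe137,-23.73,-24.86,-22.425,-24.102,-24.51,-21.75,-23.16,-23.97,-23.52,-22.668,-26.063,-25.343,-19.972
Gln97,-10.46,-10.55,-9.412,-10.040,-10.67,-7.77,-8.51,-10.58,-10.91,-7.796,-10.135,-11.251,-10.409
Glu53,-9.87,-10.53,-8.544,-6.823,-9.00,-9.34,-9.68,-10.89,-8.61,-9.036,-10.741,-11.348,-8.230
Phe96,-10.30,-10.03,-10.662,-10.039,-9.60,-10.57,-10.71,-10.98,-11.17,-9.935,-9.887,-9.895,-11.919
Arg128,-10.32,-9.83,-8.098,-8.338,-9.55,-6.34,-5.62,-5.95,-5.61,-6.320,-6.922,-8.340,-6.112
Trp58,-8.89,-9.15,-10.177,-10.736,-7.17,-10.73,-9.18,-10.52,-8.59,-10.828,-8.875,-9.480,-10.151
Asp133,-7.89,-8.05,-7.168,-7.856,-6.42,-4.07,-6.89,-8.08,-7.76,-4.878,-7.972,-8.040,-7.635
Ile30,-7.03,-7.19,-6.473,-5.779,-6.80,-6.43,-4.45,-2.43,-4.16,-4.224,-6.875,-7.546,-4.279
Tyr86,-7.50,-7.07,-8.099,-7.299,-5.50,-7.42,-7.18,-6.02,-4.28,-6.2,-5.787,-4.994,-7.296
Glu197,-3.19,-6.44,-2.983,-5.422,-6.16,-5.16,-5.50,-2.56,-2.75,-3.092,-5.961,-6.378,-3.423
Leu82,-5.34,-5.03,-6.464,-6.028,-2.02,-5.05,-4.37,-4.37,-3.96,-4.592,-5.804,-5.372,-6.131
Val55,-2.40,-2.71,-2.405,-3.650,-1.65,-3.55,-3.62,-3.13,-2.95,-4.163,2.626,-2.361,-2.248
Met85,-2.03,-2.01,-1.965,-1.903,-2.02,-1.61,-3.62,-3.13,-2.95,-1.950,-1.864,-2.002,-2.471
Ala100,-1.53,-1.66,-1.467,-1.367,-1.29,-1.29,-1.49,-1.49,-1.65,-1.524,-1.418,-1.858,-1.955
Arg104,-1.31,-1.38,-1.359,-1.219,-1.26,-1.21,-0.96,-1.39,-1.30,-1.387,-1.365,-1.744,-0.895
Leu141,0.00,0.00,0,0,-0.36,0.00,0.00,-0.34,-0.47,0,0,0,-0.330
Arg194,0.00,0.00,-0.405,0,0.00,-0.33,0.00,0.00,0.00,0,0,0,0
Ile200,-0.48,-0.46,0,-0.47,-0.52,-0.33,-0.31,0.00,0.00,0,-0.573,-0.539,-0.420
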