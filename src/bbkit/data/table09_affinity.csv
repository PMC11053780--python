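ligand_id,total_energy,protein_ligand,steric,hydrogen_bonding,mg_ligand,gehlhaar_kJ_mol,prodigy_kcal_mol
Ara-C,-105.083,-120.891,-103.105,-19.582,-0.149,-25.40,-6.90
2'-deoxycytidine 1P60,-101.556,-114.636,-100.597,-14.040,0,-23.07,-6.84
2'-deoxycytidine 1P61,-110.763,-114.816,-101.318,-13.498,0,-23.62,-6.75
2'-deoxycytidine,-99.252,-111.000,-97.634,-15.221,-0.047,-24.58,-6.81
cytidine,-94.384,-105.813,-97.468,-12.397,-0.300,-21.82,-6.87
5-azacytidine,-99.241,-107.250,-95.089,-12.667,-0.225,-21.30,-6.06
3'-deoxycytidine,-101.853,-109.095,-97.641,-12.498,-0.176,-22.37,-6.84
Zalcitabine,-96.519,-103.851,-94.237,-10.000,-0.073,-24.18,-6.70
3'-dehydro-dideoxycytidine,-102.211,-101.898,95.288,-11.310,-0.313,-22.16,-6.79
Gemcitabine 1P62,-96.221,-116.96,-102.44,-14.821,-0.094,-30.76,-7.54
Gemcitabine,-100.881,-121.854,-104.982,-16.872,-0.153,-31.56,-7.33
Decitabine,-96.171,-108.103,-93.800,-14.299,-0.049,-23.62,-6.30
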