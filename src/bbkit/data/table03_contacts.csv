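structure_id,compound,temperature_K,CC,HH,NN,OO,CH,CN,CO,NH,OH,NO
ara_c,Ara-C,295,0,41.5,0,0.2,8.8,1.0,4.1,12,31.2,2.6
cytidine_alpha,cytidine alpha,295,2.8,48.7,0.7,1.2,3.3,1.7,1.9,8.7,29.3,1.8
cytidine_beta_1,cytidine beta,295,0.2,44.3,0.3,0.5,7.6,1.0,3.8,9.7,30.6,2.1
cytidine_beta_2,cytidine beta,297.2,0.1,44.8,0.4,0.4,7.9,0.6,2.0,10.1,30.0,2.1
cytidine_beta_3,cytidine beta,2,0.1,44.6,0.5,0.2,7.8,0.8,4.1,9.8,30.0,2.2
cytidine_beta_4,cytidine beta,293,0.8,42.5,0.6,0.4,6.9,0.9,4.0,9.9,32.0,2.0
cytidine_beta_5,cytidine beta,295,0.2,44.2,0.5,0.4,8.1,0.9,3.5,10.2,30.2,1.9
deoxycytidine_2p_alpha,2'-deoxycytidine alpha,100,1.0,44.2,0,0,9.5,0.3,0.1,13.4,31.2,0.3
deoxycytidine_2p_beta,2'-deoxycytidine beta,295,0,43.4,0,0.1,7.8,0.0,1.2,13,33.8,0.7
deoxycytidine_3p,3'-deoxycytidine,295,1.7,45.2,0,2.7,8.9,1.2,0.5,10.2,26.0,3.7
zalcitabine_1,Zalcitabine,295,0,48.7,0,0.5,12.6,0,0.9,13.7,22.0,0.8
zalcitabine_2,Zalcitabine,295,0,49,0,0.4,12.6,0.0,0.8,13.9,22.5,0.8
decitabine,Decitabine,150,0,42.8,0.9,0.5,6.1,1.6,2.2,17.8,25.0,3.2
cytosine_i_1,cytosine form I,295,2.9,31.7,0.3,0.1,11.2,5.1,2.3,19.6,25.0,1.7
cytosine_i_2,cytosine form I,295,3.3,32.6,0.4,0.1,10.2,5.3,2.3,19.1,25.1,1.6
cytosine_i_3,cytosine form I,293,3.7,32.2,0.1,0.2,9.5,5,2.7,20.4,24.2,1.9
cytosine_ii,cytosine form II,294,1.2,30.5,0.5,0,16.4,0.8,2.6,23.2,22.7,2.2
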