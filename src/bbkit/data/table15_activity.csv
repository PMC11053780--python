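ligand_id,biological_activity,spectrum
Ara-C,anti-leukemic (DNA RNA),AML ALL CML
2'-deoxycytidine,DNA component,natural
cytidine,RNA component,natural; anti-depressant
5-azacytidine,anti-leukemic (RNA DNA),MDS JMML
3'-deoxycytidine,anti-viral; anticancer (DNA),NHL
Zalcitabine,anti-retroviral,HIV/AIDS
3'-dehydro-dideoxycytidine,anti-viral,metabolite
Gemcitabine,anti-neoplastic; anti-cancer; anti-tumor; anti-viral,HEV; pancreatic ovarian NSCLC
Decitabine,anti-leukemic (DNA),MDS AML HPV
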