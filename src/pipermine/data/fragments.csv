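kind,smiles
core,c1ccc({R1})cc1{R2}
core,COc1cc({R1})ccc1O{R2}
core,c1ccnc({R1})c1{R2}
core,c1cc({R1})c2[nH]cc({R2})c2c1
core,O=c1ccc2cc({R1})c({R2})cc2o1
core,COC1=CC(=O)OC(C1)C=Cc1ccc({R1})cc1{R2}
core,O=C(N1CCCCC1)C=Cc1ccc({R1})cc1{R2}
core,c1cc2OCOc2cc1C=CC(=O)N({R1})C{R2}
core,CC(C)=CCCC(C)({R1})CCC=C(C)C{R2}
core,O=C(O{R1})c1ccccc1{R2}
core,COc1ccc(C=CC(=O)C{R1})cc1{R2}
core,CC1CCC2C(C1)CCC2({R1})C{R2}
substituent,[H]
substituent,F
substituent,Cl
substituent,Br
substituent,O
substituent,OC
substituent,OCC
substituent,N
substituent,N(C)C
substituent,C#N
substituent,C(=O)N
substituent,C(=O)OC
substituent,CO
substituent,CCN
substituent,C(C)C
substituent,OCC=C
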