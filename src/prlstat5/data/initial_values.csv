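name,species,value,units,sampled,description
RJ,RJ,0.2921,nM,1,initial PRLR:JAK2 complex on the membrane (steady state k1/kdeg_RJ)
SHP2,SHP2,100.0,nM,1,initial receptor-level phosphatase SHP-2
PPX,PPX,50.0,nM,1,initial cytosolic phosphatase
PPN,PPN,60.0,nM,1,initial nuclear phosphatase
STAT5A,STAT5A,400.0,nM,1,initial cytosolic unphosphorylated STAT5A
STAT5B,STAT5B,400.0,nM,1,initial cytosolic unphosphorylated STAT5B
STAT5A_nuc,STAT5A_nuc,100.0,nM,1,initial nuclear unphosphorylated STAT5A (basal nuclear pool)
STAT5B_nuc,STAT5B_nuc,100.0,nM,1,initial nuclear unphosphorylated STAT5B (basal nuclear pool)
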