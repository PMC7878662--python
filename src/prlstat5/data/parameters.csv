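name,value,units,module,sampled,description
k1,0.0045,nM/min,core,1,synthesis rate of the PRLR:JAK2 complex RJ (balances kdeg_RJ at the baseline RJ level)
k2,0.04,1/(nM*min),core,1,PRL ligand binding on-rate to RJ
k3,1.0,1/(nM*min),core,1,receptor-complex dimerization on-rate (PRL:RJ + RJ)
k_3,0.05,1/min,core,1,receptor-complex dimerization off-rate
k4,1.0,1/min,core,1,activation rate of the dimerized complex (JAK2 trans-phosphorylation)
k5,0.2,1/(nM*min),core,1,STAT5 binding rate to the activated receptor complex
k_5,0.2,1/min,core,1,STAT5 unbinding rate from the activated receptor complex
k6,2.0,1/min,core,1,phosphorylation/release rate of receptor-docked STAT5
k7,0.002,1/(nM*min),core,1,SHP-2 catalytic dephosphorylation rate of the activated receptor
k8A,0.05,1/(nM*min),core,1,homodimerization rate of cytosolic pSTAT5A
k8B,0.05,1/(nM*min),core,1,homodimerization rate of cytosolic pSTAT5B
k8AB,0.05,1/(nM*min),core,1,heterodimerization rate of cytosolic pSTAT5A/pSTAT5B
k11,0.002,1/(nM*min),core,1,binding rate of cytosolic phosphatase PPX to pSTAT5
k12,0.1,1/min,core,1,dephosphorylating release rate of PPX-bound pSTAT5
k14A,0.06,1/min,core,1,nuclear import rate of pSTAT5A homodimers
k14B,0.06,1/min,core,1,nuclear import rate of pSTAT5B homodimers
k14AB,0.06,1/min,core,1,nuclear import rate of pSTAT5A/B heterodimers
k16,0.0015,1/(nM*min),core,1,PPN-mediated dissociative dephosphorylation rate of nuclear pSTAT5 dimers
k17A,0.003,1/min,core,1,nuclear export rate of unphosphorylated STAT5A
k17B,0.003,1/min,core,1,nuclear export rate of unphosphorylated STAT5B
kdeg_RJ,0.0154033,1/min,core,1,degradation rate of unbound RJ (half-life 45 min on the membrane)
kdeg_PRL,0.0021004,1/min,core,1,first-order PRL degradation rate (half-life 5.5 h)
v_bcl,0.0008,nM/min,core,1,maximal Bcl-xL mRNA transcription rate driven by nuclear pSTAT5 dimers
K_bcl,20.0,nM,core,1,half-saturation constant of Bcl-xL transcription in nuclear dimer concentration
a0_bcl,4e-05,nM/min,core,1,basal (STAT5-independent) Bcl-xL mRNA transcription rate
kdeg_mbcl,0.002,1/min,core,1,Bcl-xL mRNA degradation rate
ktl_bcl,0.05,1/min,core,1,Bcl-xL translation rate per mRNA
kdeg_bcl,0.001,1/min,core,1,Bcl-xL protein degradation rate
deg_ratio,6.0,dimensionless,internalization,1,ratio of ligand-bound to unbound receptor-complex degradation rate
v_socs,0.04,nM/min,socs,1,maximal SOCS mRNA transcription rate driven by nuclear pSTAT5 dimers
K_socs,100.0,nM,socs,1,half-saturation constant of SOCS transcription in nuclear dimer concentration
kdeg_msocs,0.03,1/min,socs,1,SOCS mRNA degradation rate
ktl_socs,0.5,1/min,socs,1,SOCS translation rate per mRNA
kdeg_socs,0.01,1/min,socs,1,free SOCS protein degradation rate
ksocs_on,0.05,1/(nM*min),socs,1,SOCS binding rate to ligand-bound receptor:JAK2 complexes
kdeg_socsr,0.1,1/min,socs,1,degradation rate of SOCS-bound receptor complexes (ubiquitination targeting)
k30a,0.03,nM/min,upregulation,1,maximal PRLR mRNA transcription rate driven by nuclear pSTAT5 dimers
K30,100.0,nM,upregulation,1,half-saturation constant of PRLR transcription in nuclear dimer concentration
kdeg_mprlr,0.0015,1/min,upregulation,1,PRLR mRNA degradation rate
ktl_prlr,0.05,1/min,upregulation,1,PRLR translation rate per mRNA
kassoc_prlr,0.5,1/min,upregulation,1,association rate of nascent PRLR with JAK2 to form new RJ
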