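variable,PREC,WD,SDD,SOLR,pH,WTEMP,WIND,TN,TP,DO,DTP,PO4-P,NO3-N,NH4-N,TSS
PREC,1.0,0.07,0.0,0.41,0.1,0.6,0.25,0.0,0.19,-0.57,0.09,0.08,-0.09,-0.12,0.07
WD,0.07,1.0,-0.13,-0.01,0.25,0.01,0.2,0.16,0.18,-0.01,0.16,0.16,0.12,0.03,0.04
SDD,0.0,-0.13,1.0,-0.08,0.05,0.1,-0.03,-0.15,-0.09,-0.19,0.02,0.07,-0.15,0.0,-0.29
SOLR,0.41,-0.01,-0.08,1.0,0.12,0.69,-0.07,0.2,0.1,-0.45,-0.06,0.0,0.17,-0.12,0.09
pH,0.1,0.25,0.05,0.12,1.0,0.44,0.07,-0.18,0.33,-0.18,0.04,0.12,-0.36,-0.21,-0.07
WTEMP,0.6,0.01,0.1,0.69,0.44,1.0,0.1,-0.2,0.17,-0.78,-0.03,0.06,-0.29,-0.26,-0.08
WIND,0.25,0.2,-0.03,-0.07,0.07,0.1,1.0,-0.02,0.0,-0.2,-0.01,-0.05,-0.01,-0.03,0.22
TN,0.0,0.16,-0.15,0.2,-0.18,-0.2,-0.02,1.0,0.39,0.14,0.54,0.48,0.9,0.65,0.12
TP,0.19,0.18,-0.09,0.1,0.33,0.17,0.0,0.39,1.0,-0.12,0.73,0.74,0.08,0.29,0.19
DO,-0.57,-0.01,-0.19,-0.45,-0.18,-0.78,-0.2,0.14,-0.12,1.0,-0.01,-0.1,0.15,0.13,0.0
DTP,0.09,0.16,0.02,-0.06,0.04,-0.03,-0.01,0.54,0.73,-0.01,1.0,0.94,0.33,0.57,-0.07
PO4-P,0.08,0.16,0.07,0.0,0.12,0.06,-0.05,0.48,0.74,-0.1,0.94,1.0,0.27,0.52,-0.06
NO3-N,-0.09,0.12,-0.15,0.17,-0.36,-0.29,-0.01,0.9,0.08,0.15,0.33,0.27,1.0,0.5,0.13
NH4-N,-0.12,0.03,0.0,-0.12,-0.21,-0.26,-0.03,0.65,0.29,0.13,0.57,0.52,0.5,1.0,-0.03
TSS,0.07,0.04,-0.29,0.09,-0.07,-0.08,0.22,0.12,0.19,0.0,-0.07,-0.06,0.13,-0.03,1.0
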