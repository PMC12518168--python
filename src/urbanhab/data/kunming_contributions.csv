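variable,contribution_pct,permutation_importance_pct,climatic
Bio7,30.8,0.4,1
Bio17,21.5,0.9,1
Bio2,12.6,2.6,1
Bio13,12.5,42.7,1
Bio12,5.2,8.2,1
Bio19,3.9,0.4,1
Bio15,2.7,29.2,0
Bio4,1.9,0.6,0
Bio14,1.7,0.2,0
Bio8,0.9,12.1,0
Bio9,0.8,0,0
Bio10,0.8,1.1,0
Bio3,0.7,1.7,0
LU,0.7,0,0
NPP,0.7,0,0
ASP,0.6,0,0
PD,0.5,0,0
RI,0.5,0,0
Bio6,0.3,0,0
Bio11,0.3,0,0
ALT,0.3,0,0
NDVI,0.2,0,0
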