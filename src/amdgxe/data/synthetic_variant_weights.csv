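variant_id,risk_allele,beta,is_major
rs570618,T,0.867,True
rs10922109,C,0.968,True
rs429608,G,0.562,True
rs3750846,C,1.03,True
rs2230199,C,0.405,True
synvar01,C,0.048,False
synvar02,G,0.056,False
synvar03,T,0.064,False
synvar04,A,0.072,False
synvar05,C,0.08,False
synvar06,G,0.088,False
synvar07,T,0.096,False
synvar08,A,0.104,False
synvar09,C,0.112,False
synvar10,G,0.12,False
synvar11,T,0.128,False
synvar12,A,0.136,False
synvar13,C,0.144,False
synvar14,G,0.152,False
synvar15,T,0.16,False
synvar16,A,0.168,False
synvar17,C,0.176,False
synvar18,G,0.184,False
synvar19,T,0.192,False
synvar20,A,0.2,False
synvar21,C,0.208,False
synvar22,G,0.216,False
synvar23,T,0.224,False
synvar24,A,0.232,False
synvar25,C,0.24,False
synvar26,G,0.248,False
synvar27,T,0.256,False
synvar28,A,0.264,False
synvar29,C,0.272,False
synvar30,G,0.28,False
synvar31,T,0.288,False
synvar32,A,0.296,False
synvar33,C,0.304,False
synvar34,G,0.312,False
synvar35,T,0.32,False
synvar36,A,0.328,False
synvar37,C,0.336,False
synvar38,G,0.344,False
synvar39,T,0.352,False
synvar40,A,0.36,False
synvar41,C,0.368,False
synvar42,G,0.376,False
synvar43,T,0.384,False
synvar44,A,0.392,False
synvar45,C,0.4,False
synvar46,G,0.408,False
synvar47,T,0.416,False
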