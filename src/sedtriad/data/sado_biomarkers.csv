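station,species,biomarker,mean,sd
Sado 1,clam,CAT,24.75,22.37
Sado 1,clam,LPO,0.002,0.001
Sado 1,fish,CAT,24.54,21.94
Sado 1,fish,GST,0.12,0.11
Sado 1,fish,LPO,1.76,1.05
Sado 1,cuttlefish,GST,0.005,0.002
Sado 1,cuttlefish,GSHt,0.11,0.13
Sado 1,cuttlefish,GSH/GSSG,2.08,2.39
Sado 1,cuttlefish,LPO,0.69,0.38
Sado 2,clam,CAT,33.37,27.84
Sado 2,clam,LPO,0.003,0.002
Sado 2,fish,CAT,46.91,26.23
Sado 2,fish,GST,0.31,0.14
Sado 2,fish,LPO,1.26,0.72
Sado 2,cuttlefish,GST,0.003,0.001
Sado 2,cuttlefish,GSHt,0.04,0.08
Sado 2,cuttlefish,GSH/GSSG,2.22,2.02
Sado 2,cuttlefish,LPO,0.57,0.32
Reference,clam,CAT,18.70,9.39
Reference,clam,LPO,0.001,0.000
Reference,fish,CAT,25.34,20.64
Reference,fish,GST,0.21,0.09
Reference,fish,LPO,1.05,0.52
Reference,cuttlefish,GST,0.002,0.001
Reference,cuttlefish,GSHt,0.04,0.03
Reference,cuttlefish,GSH/GSSG,2.82,1.73
Reference,cuttlefish,LPO,0.23,0.09
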