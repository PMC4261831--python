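analyte,pel,units,class
As,41.6,ug/g,metal
Cr,160,ug/g,metal
Ni,42.8,ug/g,metal
Cu,108,ug/g,metal
Zn,271,ug/g,metal
Cd,4.21,ug/g,metal
Pb,112,ug/g,metal
tPAH,16770,ng/g,organic
tDDT,51.7,ng/g,organic
tPCB,189,ng/g,organic
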