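site,analyte,mean,sd,units
R,As,0.34,0.26,ug/g
R,Se,1.84,0.84,ug/g
R,Cr,2.36,0.36,ug/g
R,Ni,4.10,1.66,ug/g
R,Cu,4.51,1.05,ug/g
R,Zn,13.10,1.51,ug/g
R,Cd,0.03,0.02,ug/g
R,Pb,3.50,0.48,ug/g
R,tPAH,19.60,3.33,ng/g
R,tDDT,0.02,0.00,ng/g
R,tPCB,0.05,0.01,ng/g
N1,As,23.98,0.48,ug/g
N1,Se,1.21,0.02,ug/g
N1,Cr,80.73,1.61,ug/g
N1,Ni,33.30,0.67,ug/g
N1,Cu,172.72,3.45,ug/g
N1,Zn,364.83,7.30,ug/g
N1,Cd,0.26,0.01,ug/g
N1,Pb,55.19,1.10,ug/g
N1,tPAH,1365.20,232.08,ng/g
N1,tDDT,0.37,0.06,ng/g
N1,tPCB,7.91,1.34,ng/g
N2,As,19.7,5.21,ug/g
N2,Se,1.92,1.45,ug/g
N2,Cr,77.67,4.57,ug/g
N2,Ni,16.67,1.1,ug/g
N2,Cu,178.64,7.01,ug/g
N2,Zn,327.51,1.16,ug/g
N2,Cd,0.27,0.03,ug/g
N2,Pb,56.45,3.1,ug/g
N2,tPAH,1076.98,183.09,ng/g
N2,tDDT,1.22,0.21,ng/g
N2,tPCB,5.37,0.91,ng/g
S1,As,26.44,2.68,ug/g
S1,Se,0.59,0.21,ug/g
S1,Cr,62.22,4.45,ug/g
S1,Ni,17.15,1.21,ug/g
S1,Cu,74.15,13.16,ug/g
S1,Zn,269.79,7.81,ug/g
S1,Cd,0.33,0.13,ug/g
S1,Pb,25.3,0.91,ug/g
S1,tPAH,215.03,36.55,ng/g
S1,tDDT,0.21,0.04,ng/g
S1,tPCB,0.26,0.04,ng/g
S2,As,25.02,8.84,ug/g
S2,Se,0.72,0.08,ug/g
S2,Cr,87.61,2.97,ug/g
S2,Ni,22.79,9.47,ug/g
S2,Cu,92.3,5.63,ug/g
S2,Zn,385.11,35.69,ug/g
S2,Cd,0.43,0.19,ug/g
S2,Pb,32.7,1.21,ug/g
S2,tPAH,82.47,14.02,ng/g
S2,tDDT,0.13,0.02,ng/g
S2,tPCB,0.27,0.05,ng/g
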