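site,x,y
R,2.0,1.0
N1,1.0,4.5
N2,2.2,5.0
S1,5.5,2.0
S2,6.5,1.2
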