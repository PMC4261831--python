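assay,site,fraction,ec50,ci_low,ci_high,status
viability,R,1,,,,nd
viability,R,2,,,,nd
viability,R,3,,,,nd
viability,R,4,,,,nd
viability,N1,1,39.8,34.3,45.2,estimable
viability,N1,2,,,,na
viability,N1,3,,,,na
viability,N1,4,,,,na
viability,N2,1,88.7,82.1,95.4,estimable
viability,N2,2,,,,nd
viability,N2,3,,,,nd
viability,N2,4,265.3,158.5,372.0,estimable
viability,S1,1,180.0,162.7,197.3,estimable
viability,S1,2,,,,nd
viability,S1,3,,,,nd
viability,S1,4,,,,nd
viability,S2,1,223.5,152.5,294.6,estimable
viability,S2,2,,,,nd
viability,S2,3,,,,nd
viability,S2,4,160.9,70.1,251.8,estimable
comet,R,1,,,,nd
comet,R,2,,,,nd
comet,R,3,,,,nd
comet,R,4,,,,nd
comet,N1,1,82.0,34.8,129.1,estimable
comet,N1,2,,,,na
comet,N1,3,,,,na
comet,N1,4,,,,na
comet,N2,1,131.6,103.6,159.6,estimable
comet,N2,2,,,,nd
comet,N2,3,,,,nd
comet,N2,4,195.6,19.1,374.1,estimable
comet,S1,1,364.5,238.2,490.7,estimable
comet,S1,2,,,,nd
comet,S1,3,,,,nd
comet,S1,4,223.9,168.4,279.4,estimable
comet,S2,1,,,,nd
comet,S2,2,,,,nd
comet,S2,3,,,,nd
comet,S2,4,,,,nd
comet_fpg,R,1,,,,nd
comet_fpg,R,2,,,,nd
comet_fpg,R,3,,,,nd
comet_fpg,R,4,,,,nd
comet_fpg,N1,1,65.4,59.6,71.2,estimable
comet_fpg,N1,2,,,,na
comet_fpg,N1,3,,,,na
comet_fpg,N1,4,,,,na
comet_fpg,N2,1,72.6,53.2,91.9,estimable
comet_fpg,N2,2,175.5,99.0,252.0,estimable
comet_fpg,N2,3,354.6,86.5,622.7,estimable
comet_fpg,N2,4,127.8,72.3,183.3,estimable
comet_fpg,S1,1,97.1,90.2,104.0,estimable
comet_fpg,S1,2,,,,nd
comet_fpg,S1,3,,,,nd
comet_fpg,S1,4,136.4,117.4,155.4,estimable
comet_fpg,S2,1,104.1,73.0,135.2,estimable
comet_fpg,S2,2,,,,nd
comet_fpg,S2,3,,,,nd
comet_fpg,S2,4,,,,nd
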