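investigator,year,country,mz_concordant,mz_total,dz_concordant,dz_total,age_low,age_high,mean_onset_age
Rosanoff et al.,1934,USA,28,41,15,101,,,
Essen-Moller,1941,Sweden,6,11,4,27,,,
Kallmann,1946,USA,120,174,53,517,15,45,23.8
Slater,1953,UK,24,37,10,112,,,
Inouye,1961,Japan,33,55,2,17,,,
Harvald and Hauge,1965,Denmark,4,9,6,62,,,
Gottesman and Shields,1966,UK,10,24,3,33,19,64,
Kringlen,1966,Norway,19,50,13,94,,,
Hoffer and Pollin,1970,USA,11,80,6,145,38,48,
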