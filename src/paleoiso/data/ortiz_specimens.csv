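burial_id,site,collagen_yield,wtC,wtN,cn_atomic,d13C_co,d15N_co,apatite_yield,d13C_ap,d18O_ap
B1,Ortiz,2.6,31.6,10.2,3.6,-14.9,9.5,43.6,-6.3,-1.7
B2,Ortiz,3.2,39.7,13.6,3.4,-15.5,9.4,64.6,-8.4,-1.5
B3,Ortiz,2.7,6.9,2.3,3.5,-15.7,7.2,63.3,-6.4,-2.2
B4,Ortiz,3.2,40.8,14.0,3.4,-15.1,9.3,40.5,-5.7,-2.0
B5,Ortiz,1.7,,,,,,,,
Maruca2B,Maruca,1.3,30.2,10.2,3.5,-18.3,8.9,,-8.8,
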