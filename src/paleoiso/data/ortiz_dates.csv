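lab_code,burial_id,cra,sigma,d13C_reported,deltaR,deltaR_sd
Beta-552439,B1,2920,30,-14.9,-138,23
Beta-581537,B2,2800,30,-15.5,-138,23
Beta-587944,B3,3460,30,-15.7,-138,23
Beta-552440,B4,3110,30,-15.1,-138,23
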