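burial_id,tooth,ratio,ci95
B1,Left mandibular M2,0.70816,0.00003
B3,Right mandibular M1,0.70803,0.00005
B4,Left maxillary M1,0.70797,0.00006
B5,Lower M,0.70756,0.00004
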