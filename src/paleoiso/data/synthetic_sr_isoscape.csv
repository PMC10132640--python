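# SYNTHETIC bioavailable-Sr envelope fixture. Not measured data: placeholder
# ranges for exercising locality screening; replace with published
# bioavailable 87Sr/86Sr tables for real provenance work.
region,ratio_min,ratio_max
southwest_puerto_rico,0.7070,0.7090
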