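name,n_items,protein_pct,protein_pct_sd,energy_pct,energy_pct_sd,d13C_bulk,d13C_bulk_sd,d13C_protein,d13C_protein_sd,d13C_energy,d13C_energy_sd,d15N_protein,d15N_protein_sd
C3,67,14,12,86,14,-25.5,1.7,-26.5,1.7,-25.3,1.7,3.3,2.1
C4CAM,20,14,12,86,14,-10.4,1.3,-11.4,1.3,-10.2,1.3,5.1,2.9
FWTERR,115,73,14,27,15,-19.8,2.9,-17.6,2.9,-25.8,2.9,6.2,2.7
M1,131,76,15,24,17,-13.9,2.1,-12.7,2.1,-17.8,2.1,13.0,2.7
M2,278,76,15,24,17,-10.7,3.3,-9.5,3.3,-14.6,3.3,5.9,3.0
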