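receptor,ligand,value_kcal_mol,uncertainty_2sigma
TEMOA,G1,-6.65,0.32
TEMOA,G2p,-12.10,0.26
TEMOA,G3,-8.80,0.32
TEMOA,G4,-8.18,0.32
TEMOA,G5,-7.97,0.32
TEETOA,G1,-0.63,0.32
TEETOA,G2p,-8.23,0.26
TEETOA,G3,-1.96,0.32
TEETOA,G4,-2.23,0.32
TEETOA,G5,-2.64,0.32
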