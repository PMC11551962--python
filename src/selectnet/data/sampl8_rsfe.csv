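kind,receptor_a,ligand_a,receptor_b,ligand_b,value_kcal_mol,uncertainty_2sigma
RSFE,TEMOA,G1,TEETOA,G2p,1.27,0.30
RSFE,TEMOA,G1,TEETOA,G3,-0.92,0.28
RSFE,TEMOA,G1,TEETOA,G4,-0.63,0.26
RSFE,TEMOA,G1,TEETOA,G5,-0.38,0.28
RSFE,TEMOA,G2p,TEETOA,G3,-2.30,0.32
RSFE,TEMOA,G2p,TEETOA,G4,-1.70,0.30
RSFE,TEMOA,G2p,TEETOA,G5,-1.18,0.30
RSFE,TEMOA,G3,TEETOA,G4,0.57,0.26
RSFE,TEMOA,G3,TEETOA,G5,1.21,0.24
RSFE,TEMOA,G4,TEETOA,G5,0.48,0.22
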