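kind,receptor_a,ligand_a,receptor_b,ligand_b,value_kcal_mol,uncertainty_2sigma
RHFE,TEMOA,G1,TEETOA,G1,5.46,0.34
RHFE,TEMOA,G2p,TEETOA,G2p,3.93,0.24
RHFE,TEMOA,G3,TEETOA,G3,6.21,0.32
RHFE,TEMOA,G4,TEETOA,G4,5.51,0.32
RHFE,TEMOA,G5,TEETOA,G5,5.25,0.32
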