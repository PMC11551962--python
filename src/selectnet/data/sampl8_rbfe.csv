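kind,receptor_a,ligand_a,receptor_b,ligand_b,value_kcal_mol,uncertainty_2sigma
RBFE,TEMOA,G1,TEMOA,G2p,-5.08,0.32
RBFE,TEMOA,G1,TEMOA,G3,-1.73,0.30
RBFE,TEMOA,G1,TEMOA,G4,-1.85,0.28
RBFE,TEMOA,G1,TEMOA,G5,-1.40,0.28
RBFE,TEMOA,G2p,TEMOA,G3,3.30,0.32
RBFE,TEMOA,G2p,TEMOA,G4,3.05,0.32
RBFE,TEMOA,G2p,TEMOA,G5,3.50,0.32
RBFE,TEMOA,G3,TEMOA,G4,-0.12,0.28
RBFE,TEMOA,G3,TEMOA,G5,-0.04,0.28
RBFE,TEMOA,G4,TEMOA,G5,0.11,0.26
RBFE,TEETOA,G1,TEETOA,G2p,-6.19,0.32
RBFE,TEETOA,G1,TEETOA,G3,-0.48,0.30
RBFE,TEETOA,G1,TEETOA,G4,-1.66,0.28
RBFE,TEETOA,G1,TEETOA,G5,-1.62,0.30
RBFE,TEETOA,G2p,TEETOA,G3,5.45,0.32
RBFE,TEETOA,G2p,TEETOA,G4,4.86,0.32
RBFE,TEETOA,G2p,TEETOA,G5,4.69,0.32
RBFE,TEETOA,G3,TEETOA,G4,-0.74,0.28
RBFE,TEETOA,G3,TEETOA,G5,-0.83,0.28
RBFE,TEETOA,G4,TEETOA,G5,0.05,0.26
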