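kind,receptor_a,ligand_a,receptor_b,ligand_b,value_kcal_mol,uncertainty_2sigma
RBFE,thrombin,Am,thrombin,Bz,0.33,0.32
RBFE,trypsin,Bz,trypsin,Am,2.19,0.32
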