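kind,receptor_a,ligand_a,receptor_b,ligand_b,value_kcal_mol,uncertainty_2sigma
RSFE,trypsin,Bz,thrombin,Am,2.37,0.30
RSFE,trypsin,Am,thrombin,Bz,-2.88,0.30
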