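# Curated SMILES fragment pools for the synthetic library generator.
#
# Assembly by plain SMILES concatenation:
#   heterobifunctional = warhead + linker + e3_ligand
#   glue               = glue_core + substituent
#   other              = drug_core + substituent
#
# Every fragment is valid standalone SMILES. Fragments used in non-terminal
# position end on an sp3 C/N with a free valence; fragments used in
# non-initial position start on one, so concatenation forms a single bond.
# All pairwise/triple assemblies are verified parseable in the test suite.
drug_cores:
- CC(=O)Nc1ccc(O)cc1C
- CN1CCC(CC1)c1ccccc1OC
- COc1ccc(CCN)cc1OC
- CC(C)NCC(O)c1ccc(O)cc1C
- Fc1ccc2c(c1)c(c[nH]2)CCN
- CC1CCN(CC1)C(=O)c1ccncc1C
- CNS(=O)(=O)c1ccc(cc1)C(C)N
- COC(=O)C1CCN(C)CC1c1ccccc1
- CC(N)Cc1ccc(O)c(OC)c1
- NC(=O)c1cc(F)ccc1N1CCN(C)CC1C
- CCOC(=O)c1ccccc1NC(=O)C
- CC(O)c1ccc(Cl)cc1CN
- CN1CCC(CC1)Oc1ccccc1C
- COc1ccc(cc1)S(=O)(=O)N1CCC(C)C1
e3_ligands:
- CN1C(=O)CCC1C1CCC(=O)NC1=O
- CN1CC(=O)N(C)C1c1ccc2C(=O)NC(=O)c2c1
- COc1ccc2C(=O)N(C3CCC(=O)NC3=O)C(=O)c2c1
- CN(C)C(=O)C1CCCN1C(=O)C(N)C(C)(C)C
- CC1CCC(CN1)NC(=O)C1CC(O)CN1C(=O)C(N)C(C)C
- CN1C(=O)C2CCCCC2C1C1CCC(=O)NC1=O
- CC(NC(=O)C1CC(O)CN1)c1ccc(cc1)c1scnc1C
- CN1CCN(CC1)c1ccc2C(=O)N(C3CCC(=O)NC3=O)C(=O)c2c1
- CCOc1ccc2C(=O)N(C3CCC(=O)NC3=O)C(=O)c2c1
- CC(C)(C)C(N)C(=O)N1CC(O)CC1C(=O)NC
- CN1C(=O)CC(C1=O)N1C(=O)c2ccccc2C1=O
- CNC(=O)C1CC(O)CN1C(=O)C(NC(C)=O)C(C)(C)C
glue_cores:
- O=C1CC(N2C(=O)c3ccccc3C2=O)C(=O)N1C
- O=C1c2ccccc2C(=O)N1C1CCC(=O)NC1C
- COc1ccc(cc1)C1CC(=O)NC(=O)C1N
- O=C1c2cc(F)ccc2C(=O)N1C1CC(=O)N(C1)C
- CC1CCC(=O)N1c1ccc2C(=O)NC(=O)c2c1C
- O=C1NC(=O)C(CC1)c1ccc(cc1)N(C)C
- COc1cc2C(=O)N(C3CCC(=O)NC3=O)Cc2cc1OC
- O=C1c2ccccc2C(=O)N1C1CCN(C1)C(=O)C(C)N
- CN1C(=O)c2ccccc2C1NC(=O)C1CCNCC1C
- CC1CN(CC(=O)N1)c1ccc2C(=O)NC(=O)c2c1C
- O=C1NC(=O)C(CC1)N1CCC(C1)C(=O)NC
- COc1ccc(CN2C(=O)CCC2C2CCC(=O)NC2=O)cc1C
linkers:
- CCOCCOCC
- CCOCCOCCOCC
- CCCCCC
- CCCC
- CCOCC
- CCN(C)CC
- CCC(=O)NCC
- CCNC(=O)CC
- CCOCCOCCC
- CC1CCN(CC1)CC
- CCN1CCN(CC1)CC
- CCCOCCC
- CCCCCCCC
- CCOCCNC(=O)CC
- CCCNC(=O)CCC
- CC(C)COCC
substituents:
- C
- CC
- CCO
- CC(C)C
- CCN(C)C
- CC(=O)NC
- COC
- CCF
- CC#N
- CCOC
- CS(C)(=O)=O
- CC1CC1
- CCN
- CC(C)O
warheads:
- CNC(=O)c1ccc(Nc2nccc(n2)c2cccnc2)cc1CN
- CC(=O)Nc1ccc(cc1)S(=O)(=O)NC
- CN(C)C(=O)c1ccc(Nc2ncnc3[nH]ccc23)cc1C
- CC1CCN(CC1)C(=O)c1ccc(F)cc1NC
- COc1cc(Nc2nccc(C)n2)ccc1C(=O)NC
- CN1CCN(CC1)c1ccc(NC(=O)c2ccccc2F)cc1C
- CC(N)c1ccc(cc1)C(=O)N1CCC(C)C1C
- CNS(=O)(=O)c1ccc(Nc2ncccn2)cc1C
- COc1ccc(NC(=O)C2CCN(C)CC2)cc1CN
- CC(=O)N1CCC(CC1)Nc1ncnc(N)c1C
- CN(C)S(=O)(=O)c1ccc(NC(C)=O)cc1CC
- CC(C)Oc1ccc(Nc2ncc(F)cn2)cc1CN
- CN1CCC(CC1)Oc1ccc(N)cc1C
- CC(=O)Nc1cc(ccc1F)C(=O)N1CCNC(C)C1C
- CNC(=O)c1cnc(Nc2ccc(F)cc2)nc1NC
- CC(C)Nc1ncnc(n1)N1CCN(CC1)C
- COC(=O)c1ccc(Nc2ncccn2)cc1CN
- CN(C)c1ccc(cc1)C(=O)NC1CCNCC1C
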