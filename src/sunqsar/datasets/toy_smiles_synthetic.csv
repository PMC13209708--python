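name,smiles
syn-benzimidazole-1,c1ccc2[nH]cnc2c1
syn-benzimidazole-2,Cc1nc2ccccc2[nH]1
syn-triazine-1,c1ncncn1
syn-triazine-amine,Nc1ncncn1
syn-triazine-dianiline,c1ccc(Nc2ncncn2)cc1
syn-aniline,Nc1ccccc1
syn-paba-like,Nc1ccc(C(=O)O)cc1
syn-benzoic-acid,OC(=O)c1ccccc1
syn-salicylate,OC(=O)c1ccccc1O
syn-phenol,Oc1ccccc1
syn-cresol,Cc1ccc(O)cc1
syn-sulfonic,OS(=O)(=O)c1ccccc1
syn-sulfanilic,Nc1ccc(S(=O)(=O)O)cc1
syn-octane,CCCCCCCC
syn-decanoate,CCCCCCCCCC(=O)O
syn-hexyl-benzene,CCCCCCc1ccccc1
syn-octyl-ester,CCCCCCCCOC(=O)c1ccccc1
syn-benzophenone,O=C(c1ccccc1)c1ccccc1
syn-methoxyphenone,COc1ccc(C(=O)c2ccccc2)cc1
syn-cinnamate,COC(=O)C=Cc1ccccc1
syn-acridine-amine,Nc1c2ccccc2nc2ccccc12
syn-tetrahydroacridine,Nc1c2c(nc3ccccc13)CCCC2
syn-pyridine,c1ccncc1
syn-imidazole,c1c[nH]cn1
syn-naphthalene,c1ccc2ccccc2c1
syn-anisole,COc1ccccc1
syn-toluene,Cc1ccccc1
syn-diethylaniline,CCN(CC)c1ccccc1
syn-camphor-like,CC1(C)C2CCC1(C)C(=O)C2
syn-nitrile,N#Cc1ccccc1
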