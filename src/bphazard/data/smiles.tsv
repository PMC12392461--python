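TCBPA	CC(C)(c1cc(Cl)c(O)c(Cl)c1)c1cc(Cl)c(O)c(Cl)c1
TBBPA	CC(C)(c1cc(Br)c(O)c(Br)c1)c1cc(Br)c(O)c(Br)c1
TMBPF	Cc1cc(Cc2cc(C)c(O)c(C)c2)cc(C)c1O
BPPH	CC(C)(c1ccc(-c2ccccc2)cc1O)c1ccc(-c2ccccc2)cc1O
BPG	CC(C)c1cc(C(C)(C)c2ccc(O)c(C(C)C)c2)ccc1O
BADGE	CC(C)(c1ccc(OCC2CO2)cc1)c1ccc(OCC2CO2)cc1
BPP	CC(C)(c1ccc(O)cc1)c1ccc(C(C)(C)c2ccc(O)cc2)cc1
Pergafast	Cc1ccc(S(=O)(=O)NC(=O)Nc2cccc(OS(=O)(=O)c3ccc(C)cc3)c2)cc1
BTUM	Cc1ccc(S(=O)(=O)NC(=O)Nc2ccc(Cc3ccc(NC(=O)NS(=O)(=O)c4ccc(C)cc4)cc3)cc2)cc1
BPT	Oc1ccc(Sc2ccc(O)cc2)cc1
BPF	Oc1ccc(Cc2ccc(O)cc2)cc1
BPZ	Oc1ccc(C2(c3ccc(O)cc3)CCCCC2)cc1
BzPB	O=C(OCc1ccccc1)c1ccc(O)cc1
Bz	COC(=O)C(c1ccc(O)cc1)c1ccc(O)cc1
BPAP	CC(c1ccccc1)(c1ccc(O)cc1)c1ccc(O)cc1
BPAF	FC(F)(F)C(c1ccc(O)cc1)(c1ccc(O)cc1)C(F)(F)F
BP-MIBK	CC(CC(C)C)(c1ccc(O)cc1)c1ccc(O)cc1
BPB	CCC(C)(c1ccc(O)cc1)c1ccc(O)cc1
BPA	CC(C)(c1ccc(O)cc1)c1ccc(O)cc1
BPE	CC(c1ccc(O)cc1)c1ccc(O)cc1
BPS-MPE	O=S(=O)(c1ccc(O)cc1)c1ccc(OCc2ccccc2)cc1
BPS-MAE	C=CCOc1ccc(S(=O)(=O)c2ccc(O)cc2)cc1
D8	CC(C)Oc1ccc(S(=O)(=O)c2ccc(O)cc2)cc1
BPS	O=S(=O)(c1ccc(O)cc1)c1ccc(O)cc1
2,4-BPS	O=S(=O)(c1ccc(O)cc1)c1ccccc1O
t-TMCD	CC1(C)[C@H](O)C(C)(C)[C@@H]1O
r-TMCD	CC1(C)C(O)C(C)(C)C1O
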