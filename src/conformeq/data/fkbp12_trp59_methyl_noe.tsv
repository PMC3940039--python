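# Methyl -> Trp59 indole H-Ne1 NOE analysis of wild-type FKBP12.
# noe_exp: experimental NOESY cross-peak volumes, normalized to the maximum
#   entry and to the corresponding 1H-13C correlation peak volumes.
# dist_*: methyl carbon -> indole H-Ne1 distance (Angstrom) in the wild-type
#   (PDB 2PPN) and G89P-variant (PDB 4N19) crystal structures; interactions
#   beyond 7 A carry no predicted volume in that conformer.
# noe_s2_*: jump-model predicted volumes, normalized per structure.  The
#   wild-type Val101 CG2 prediction includes the chemically degenerate
#   Val63 CG1 methyl (~4% of the predicted volume); the wild-type Val101 CG1
#   entry is excluded from that structure's prediction despite its tabulated
#   distance.  Absolute maximum rates across the two structures stand in the
#   ratio wt/G89P = 0.28.
resnum	resname	atom	noe_exp	dist_wt	noe_s2_wt	dist_g89p	noe_s2_g89p
56	ILE	CD1	0.795	4.38	0.903	.	.
76	ILE	CD1	0.828	4.14	1.000	.	.
55	VAL	CG2	0.048	.	.	6.59	0.018
24	VAL	CG2	0.460	.	.	3.89	0.661
101	VAL	CG1	0.650	6.82	.	3.37	0.858
24	VAL	CG1	0.308	.	.	4.54	0.173
101	VAL	CG2	1.000	4.98	0.348	3.32	1.000
63	VAL	CG2	0.651	6.88	0.054	3.60	0.613
97	LEU	CD1	0.050	6.27	0.092	.	.
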