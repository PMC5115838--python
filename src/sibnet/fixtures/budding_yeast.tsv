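# Budding-yeast cell-cycle network, 11 nodes / 34 edges.
# Signed adjacency matrix of the cell-cycle regulatory network of
# Saccharomyces cerevisiae (Li, Long, Lu, Ouyang & Tang 2004, PNAS 101:4781),
# with the five self-degradation loops (Cln3, Cln1/2, Swi5, Cdc20/Cdc14,
# Mcm1/SFF) encoded as inhibitory self-edges.
# Orientation: a[i][j] = effect of node j (column) on node i (row);
# 1 = activation, -1 = inhibition, 0 = no edge.
# Node order: 1 Cln3, 2 MBF, 3 SBF, 4 Cln1/2, 5 Cdh1, 6 Swi5,
# 7 Cdc20/Cdc14, 8 Clb5/6, 9 Sic1, 10 Clb1/2, 11 Mcm1/SFF.
Cln3	MBF	SBF	Cln12	Cdh1	Swi5	Cdc20_Cdc14	Clb56	Sic1	Clb12	Mcm1_SFF
Cln3	-1	0	0	0	0	0	0	0	0	0	0
MBF	1	0	0	0	0	0	0	0	0	-1	0
SBF	1	0	0	0	0	0	0	0	0	-1	0
Cln12	0	0	1	-1	0	0	0	0	0	0	0
Cdh1	0	0	0	-1	0	0	1	-1	0	-1	0
Swi5	0	0	0	0	0	-1	1	0	0	-1	1
Cdc20_Cdc14	0	0	0	0	0	0	-1	0	0	1	1
Clb56	0	1	0	0	0	0	-1	0	-1	0	0
Sic1	0	0	0	-1	0	1	1	-1	0	-1	0
Clb12	0	0	0	0	-1	0	-1	1	-1	0	1
Mcm1_SFF	0	0	0	0	0	0	0	1	0	1	-1
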