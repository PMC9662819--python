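# Per-amino-acid property table (one row per canonical residue).
# Sources (AAindex accession or literature, per column):
#   molecular_weight  FASG760101 (free amino acid molecular weight, Da)
#   charge            KLEP840101 (net charge at pH 7)
#   hydrophobicity    KYTJ820101 (Kyte-Doolittle hydropathy)
#   aromaticity       indicator: 1 for F/W/Y/H side-chain rings, else 0
#   hydrogen_bonding  side-chain hydrogen-bond donor+acceptor count
#   polarity          GRAR740102 (Grantham polarity)
#   polarizability    CHAM820101 (Charton-Charton polarizability)
#   flexibility       VINM940101 (Vihinen normalized flexibility)
#   hydrophilicity    HOPT810101 (Hopp-Woods hydrophilicity)
#   max_sasa          Tien et al. 2013 theoretical maximum SASA (A^2)
aa	molecular_weight	charge	hydrophobicity	aromaticity	hydrogen_bonding	polarity	polarizability	flexibility	hydrophilicity	max_sasa
A	89.09	0	1.8	0	0	8.1	0.046	0.984	-0.5	129.0
R	174.20	1	-4.5	0	5	10.5	0.291	1.008	3.0	274.0
N	132.12	0	-3.5	0	4	11.6	0.134	1.048	0.2	195.0
D	133.10	-1	-3.5	0	4	13.0	0.105	1.068	3.0	193.0
C	121.15	0	2.5	0	1	5.5	0.128	0.906	-1.0	167.0
Q	146.15	0	-3.5	0	4	10.5	0.180	1.037	0.2	225.0
E	147.13	-1	-3.5	0	4	12.3	0.151	1.094	3.0	223.0
G	75.07	0	-0.4	0	0	9.0	0.000	1.031	0.0	104.0
H	155.16	0	-3.2	1	3	10.4	0.230	0.950	-0.5	224.0
I	131.17	0	4.5	0	0	5.2	0.186	0.927	-1.8	197.0
L	131.17	0	3.8	0	0	4.9	0.186	0.935	-1.8	201.0
K	146.19	1	-3.9	0	3	11.3	0.219	1.102	3.0	236.0
M	149.21	0	1.9	0	1	5.7	0.221	0.952	-1.3	224.0
F	165.19	0	2.8	1	0	5.2	0.290	0.915	-2.5	240.0
P	115.13	0	-1.6	0	0	8.0	0.131	1.049	0.0	159.0
S	105.09	0	-0.8	0	3	9.2	0.062	1.046	0.3	155.0
T	119.12	0	-0.7	0	3	8.6	0.108	0.997	-0.4	172.0
W	204.24	0	-0.9	1	1	5.4	0.409	0.904	-3.4	285.0
Y	181.19	0	-1.3	1	3	6.2	0.298	0.929	-2.3	263.0
V	117.15	0	4.2	0	0	5.9	0.140	0.931	-1.5	174.0
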