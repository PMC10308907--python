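# label	synthetic_fungal_nuclear_like
# n_codons	1000000
codon	count	frequency
AAA	38176	0.038176
AAC	22814	0.022814
AAG	34995	0.034995
AAT	21901	0.021901
ACA	15918	0.015918
ACC	16581	0.016581
ACG	14591	0.014591
ACT	15918	0.015918
AGA	7506	0.007506
AGC	14291	0.014291
AGG	6880	0.00688
AGT	13720	0.01372
ATA	12696	0.012696
ATC	13225	0.013225
ATG	18293	0.018293
ATT	12696	0.012696
CAA	19618	0.019618
CAC	15037	0.015037
CAG	17983	0.017983
CAT	14435	0.014435
CCA	12837	0.012837
CCC	13372	0.013372
CCG	11767	0.011767
CCT	12837	0.012837
CGA	7149	0.007149
CGC	7446	0.007446
CGG	6553	0.006553
CGT	7149	0.007149
CTA	12936	0.012936
CTC	13474	0.013474
CTG	11858	0.011858
CTT	12936	0.012936
GAA	30753	0.030753
GAC	30592	0.030592
GAG	28190	0.02819
GAT	29368	0.029368
GCA	18999	0.018999
GCC	19790	0.01979
GCG	17415	0.017415
GCT	18999	0.018999
GGA	18999	0.018999
GGC	19790	0.01979
GGG	17415	0.017415
GGT	18999	0.018999
GTA	17458	0.017458
GTC	18186	0.018186
GTG	16003	0.016003
GTT	17458	0.017458
TAA	1063	0.001063
TAC	17111	0.017111
TAG	974	0.000974
TAT	16426	0.016426
TCA	13720	0.01372
TCC	14291	0.014291
TCG	12576	0.012576
TCT	13720	0.01372
TGA	1012	0.001012
TGC	6741	0.006741
TGG	13211	0.013211
TGT	6471	0.006471
TTA	13582	0.013582
TTC	20740	0.02074
TTG	12450	0.01245
TTT	19910	0.01991
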