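# label	synthetic_fungal_mito_like
# n_codons	1000001
codon	count	frequency
AAA	52265	0.05226494774
AAC	14905	0.0149049851
AAG	20906	0.02090597909
AAT	29810	0.02980997019
ACA	21727	0.02172697827
ACC	10863	0.01086298914
ACG	8691	0.008690991309
ACT	21727	0.02172697827
AGA	13962	0.01396198604
AGC	9354	0.009353990646
AGG	5585	0.005584994415
AGT	18708	0.01870798129
ATA	15447	0.01544698455
ATC	7724	0.007723992276
ATG	18293	0.01829298171
ATT	15447	0.01544698455
CAA	26858	0.02685797314
CAC	9824	0.009823990176
CAG	10743	0.01074298926
CAT	19648	0.01964798035
CCA	17522	0.01752198248
CCC	8761	0.008760991239
CCG	7009	0.007008992991
CCT	17522	0.01752198248
CGA	7978	0.007977992022
CGC	3989	0.003988996011
CGG	3191	0.003190996809
CGT	7978	0.007977992022
CTA	14437	0.01443698556
CTC	7218	0.007217992782
CTG	5775	0.005774994225
CTT	14437	0.01443698556
GAA	42102	0.0421019579
GAC	19986	0.01998598001
GAG	16841	0.01684098316
GAT	39973	0.03997296003
GCA	25932	0.02593197407
GCC	12966	0.01296598703
GCG	10373	0.01037298963
GCT	25932	0.02593197407
GGA	25932	0.02593197407
GGC	12966	0.01296598703
GGG	10373	0.01037298963
GGT	25932	0.02593197407
GTA	23830	0.02382997617
GTC	11915	0.01191498809
GTG	9532	0.009531990468
GTT	23830	0.02382997617
TAA	1546	0.001545998454
TAC	11179	0.01117898882
TAG	619	0.000618999381
TAT	22358	0.02235797764
TCA	18708	0.01870798129
TCC	9354	0.009353990646
TCG	7483	0.007482992517
TCT	18708	0.01870798129
TGA	884	0.000883999116
TGC	4404	0.004403995596
TGG	13211	0.01321098679
TGT	8808	0.008807991192
TTA	25264	0.02526397474
TTC	13550	0.01354998645
TTG	10106	0.01010598989
TTT	27100	0.0270999729
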