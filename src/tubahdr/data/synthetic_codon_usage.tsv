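# synthetic codon-usage fixture (fractions sum to 1); not real mouse data
AAA	0.017511
AAC	0.021193
AAG	0.016177
AAT	0.015138
ACA	0.022347
ACC	0.015727
ACG	0.018802
ACT	0.018011
AGA	0.022339
AGC	0.013987
AGG	0.025621
AGT	0.012427
ATA	0.019333
ATC	0.018360
ATG	0.011917
ATT	0.020033
CAA	0.014465
CAC	0.010143
CAG	0.021130
CAT	0.008390
CCA	0.011022
CCC	0.016095
CCG	0.022275
CCT	0.020571
CGA	0.017390
CGC	0.007106
CGG	0.012170
CGT	0.013394
CTA	0.009922
CTC	0.006190
CTG	0.016435
CTT	0.020850
GAA	0.012923
GAC	0.022153
GAG	0.007904
GAT	0.009640
GCA	0.016284
GCC	0.012433
GCG	0.020114
GCT	0.018715
GGA	0.012833
GGC	0.008273
GGG	0.012175
GGT	0.018909
GTA	0.020454
GTC	0.012458
GTG	0.006173
GTT	0.007692
TAA	0.018257
TAC	0.012738
TAG	0.012876
TAT	0.009567
TCA	0.009482
TCC	0.021993
TCG	0.018534
TCT	0.011433
TGA	0.015771
TGC	0.016959
TGG	0.029594
TGT	0.009109
TTA	0.016863
TTC	0.021946
TTG	0.028099
TTT	0.011169
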