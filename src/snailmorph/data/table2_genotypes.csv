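genotype,haplotype,comp140766_c3_seq1,comp141987_c0_seq1,comp144295_c3_seq1,comp152737_c0_seq2,comp152973_c0_seq1,comp162701_c0_seq4,comp163630_c0_seq1,comp132525_c0_seq1,comp141103_c0_seq2,comp146583_c0_seq2,ss804270605,ss804270596,ss804270598,ss804270584,ss804270595,ss804270614
1,t/22,CC,TC,TA,AA,GG,TC,TC,CA,TT,GG,GA,AA,CC,TC,TC,TC
2,t/22,CC,TC,TA,AA,GG,TC,TC,CA,TT,GG,GG,AA,CC,TC,TC,TC
3,t/22,CC,TT,TT,AA,GG,TC,TC,CA,TT,GG,GA,AA,CC,TC,TC,TC
4,t/22,CC,TC,TA,AA,GG,TC,TC,CA,TT,GG,GA,AA,CC,CC,TC,TC
5,t/22,CC,TC,TA,AA,GG,TT,TC,CA,TT,GG,GA,AA,CC,CC,TC,TC
6,t/22,CC,TC,TA,GA,GG,TC,TC,CA,TT,GG,GA,AA,CC,CC,TC,TC
7,t/22,CC,TC,TT,AA,GG,TC,TC,CA,TT,GG,GA,AA,CC,TC,TC,TT
8,t/22,CC,TT,??,AA,GG,TT,CC,CC,TT,GG,GA,AA,CC,TT,TT,??
9,z2/37,TT,CC,AA,GG,GA,CC,TT,AA,CC,GC,AA,GA,TT,CC,CC,TT
10,z2/37,TT,CC,??,GG,AA,CC,TT,AA,CC,CC,AA,GG,TT,CC,CC,??
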