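patient,age,sex,years_education,iq,tsl_months,lesion_side,lesion_volume_cm3
1,51,F,9,94,22,R,0.13
2,45,M,13,130,0.25,L,0.06
3,40,M,18,,12,L,0.07
4,45,M,18,118,1,L,0.03
5,36,M,13,124,29,B(R>L),0.03
6,43,F,13,,12,B(L>R),0.36
7,31,M,13,112,8,R,0.12
8,53,M,12,100,1,R,2.35
9,25,F,13,101,0.5,R,0.21
10,37,M,13,118,10,R,0.2
11,57,F,13,118,60,L,0.15
12,39,M,18,130,11,R,0.26
13,32,F,18,124,2,L,0.2
14,34,M,16,118,45,B(R>L),1.13
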