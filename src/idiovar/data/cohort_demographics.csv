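patient,days,sex,age
1,201,F,41
2,150,F,50
3,174,M,54
4,179,F,33
5,172,F,43
6,205,F,60
7,199,F,44
8,150,F,45
9,188,F,38
10,156,F,33
11,203,M,42
12,170,M,21
13,154,M,53
14,160,F,48
15,143,M,50
16,150,F,35
17,199,F,32
18,179,F,53
19,178,F,27
20,173,F,67
21,178,M,26
22,151,M,62
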