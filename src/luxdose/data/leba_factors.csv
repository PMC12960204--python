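item,factor,reverse
1,F1,0
2,F1,0
3,F1,0
4,F2,1
5,F2,0
6,F2,0
7,F2,0
8,F2,0
9,F2,0
10,F3,0
11,F3,0
12,F3,0
13,F3,0
14,F3,0
15,F4,0
16,F4,0
17,F4,0
18,F4,0
19,F4,0
20,F5,0
21,F5,0
22,F5,0
23,F5,0
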