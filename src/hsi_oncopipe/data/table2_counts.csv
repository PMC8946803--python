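patient,total,tumor,non_tumor
1,7819,5065,2754
2,123,0,123
3,1678,0,1678
4,3134,0,3134
6,7102,1012,6090
7,1236,440,796
8,1663,0,1663
9,1564,31,1533
10,1382,80,1302
11,745,688,57
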