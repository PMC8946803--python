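patient,sample,tissue_type,included
1,A,Ovarian,1
1,B,Ovarian,1
1,C,Ovarian,1
1,D,Omentum,1
2,A,Mesenterium,1
3,A,Omentum,1
3,B,Ovarian,1
4,A,Omentum,1
4,B,Omentum,1
4,C,Intestines,1
5,A,Omentum,0
6,A,Ovarian,1
6,B,Ovarian,1
6,C,Intestines,1
6,D,Omentum,1
6,E,Omentum,1
7,A,Omentum,1
7,B,Ovarian,1
7,C,Ovarian,1
8,A,Omentum,1
8,B,Ovarian,1
9,A,Ovarian,1
9,B,Ovarian,1
10,A,Ovarian,1
10,B,Omentum,1
10,C,Ovarian,1
11,A,Omentum,1
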