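phone_calls,email,participants,responders,quitters
1,0,217,214,50
1,1,925,69,30
2,0,134,132,23
2,1,6,1,0
3,0,93,89,16
3,1,3,0,0
4,0,59,57,10
4,1,4,0,0
5,0,48,45,9
5,1,8,0,0
6,0,19,19,1
6,1,2,1,1
7,0,38,38,5
7,1,2,0,0
8,0,17,16,3
8,1,5,1,1
9,0,11,10,2
9,1,2,0,0
10,0,19,19,6
10,1,146,11,5
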