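piece_index,"0,-2,-4,-5,-7,-9"
1,0.591
2,0.692
3,0.753
4,0.725
5,0.373
6,0.771
7,0.633
8,0.529
9,0.848
10,0.769
11,0.627
12,0.925
13,0.875
14,1.000
15,0.660
16,0.639
17,0.053
18,0.464
19,0.625
20,0.682
21,0.667
22,0.833
23,0.468
24,0.778
25,0.424
26,0.839
27,0.739
28,0.200
29,0.671
30,0.636
31,0.200
32,0.429
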