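age,qx
0,4.12967533e-05
1,4.518575759e-05
2,4.944098875e-05
3,5.409693251e-05
4,5.91913216e-05
5,6.47654414e-05
6,7.086446433e-05
7,7.753781577e-05
8,8.483957427e-05
9,9.282890956e-05
10,0.0001015705616
11,0.000111135365
12,0.000121600822
13,0.0001330517305
14,0.0001455808698
15,0.0001592897519
16,0.0001742894429
17,0.0001907014611
18,0.0002086587609
19,0.0002283068069
20,0.0002498047512
21,0.0002733267194
22,0.0002990632181
23,0.000327222674
24,0.0003580331177
25,0.000391744025
26,0.0004286283303
27,0.0004689846294
28,0.0005131395873
29,0.0005614505721
30,0.0006143085338
31,0.0006721411534
32,0.0007354162843
33,0.0008046457151
34,0.000880389283
35,0.0009632593689
36,0.001053925811
37,0.001153121273
38,0.001261647111
39,0.001380379784
40,0.001510277848
41,0.001652389612
42,0.001807861476
43,0.001977947052
44,0.002164017112
45,0.002367570442
46,0.002590245687
47,0.002833834271
48,0.00310029448
49,0.003391766811
50,0.003710590705
51,0.004059322758
52,0.004440756551
53,0.004857944232
54,0.005314219974
55,0.005813225476
56,0.006358937659
57,0.006955698716
58,0.007608248706
59,0.008321760855
60,0.009101879767
61,0.009954762731
62,0.01088712432
63,0.01190628445
64,0.01302022018
65,0.01423762129
66,0.01556794995
67,0.01702150453
68,0.01860948776
69,0.0203440792
70,0.0222385122
71,0.02430715518
72,0.0265655972
73,0.02903073753
74,0.03172087896
75,0.03465582413
76,0.03785697442
77,0.04134743016
78,0.04515209119
79,0.04929775584
80,0.05381321664
81,0.05872935006
82,0.06407919719
83,0.06989803182
84,0.07622341126
85,0.08309520463
86,0.09055559233
87,0.09864902918
88,0.1074221628
89,0.116923697
90,0.1272041896
91,0.1383157711
92,0.1503117706
93,0.1632462338
94,0.1771733159
95,0.1921465323
96,0.2082178498
97,0.2254365995
98,0.2438481975
99,0.2634926581
100,1
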