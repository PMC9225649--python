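age,qx
0,0.0005198648234315817
1,0.000521856962366174
2,0.0005240476310021114
3,0.0005264566136232718
4,0.0005291056659912918
5,0.0005320187117799913
6,0.0005352220585751466
7,0.0005387446353918302
8,0.0005426182538483815
9,0.0005468778953536813
10,0.0005515620268962129
11,0.0005567129482817457
12,0.0005623771739484695
13,0.0005686058528009408
14,0.0005754552298427029
15,0.0005829871537681441
16,0.0005912696350790503
17,0.0006003774597538314
18,0.0006103928639870082
19,0.000621406276068659
20,0.0006335171320742683
21,0.0006468347726915624
22,0.0006614794292426618
23,0.0006775833077480309
24,0.00069529178076011
25,0.0007147646976480848
26,0.0007361778250719597
27,0.000759724430538733
28,0.0007856170231985704
29,0.0008140892674349809
30,0.0008453980863200039
31,0.0008798259736848557
32,0.0009176835353819079
33,0.0009593122823225997
34,0.0010050877000745695
35,0.0010554226222028174
36,0.001110770937175154
37,0.0011716316615241196
38,0.0012385534151069244
39,0.0013121393377338864
40,0.0013930524901862862
41,0.0014820217867261842
42,0.0015798485106562898
43,0.0016874134693267706
44,0.0018056848502522316
45,0.00193572684571941
46,0.0020787091194580665
47,0.0022359171956565227
48,0.002408763857843055
49,0.0025988016529655544
50,0.0028077366043959273
51,0.003037443246592053
52,0.0032899811037764293
53,0.0035676127452453077
54,0.0038728235607956574
55,0.004208343411237991
56,0.00457717032100069
57,0.00498259639237586
58,0.005428236133906861
59,0.00591805740865059
60,0.00645641522138396
61,0.007048088577031764
62,0.00769832065536713
63,0.008412862558988654
64,0.009198020902206339
65,0.010060709517150435
66,0.011008505559374604
67,0.012049710297480809
68,0.013193414868664877
69,0.014449571273101314
70,0.0158290688629783
71,0.017343816554605707
72,0.019006830951748932
73,0.02083233051208111
74,0.022835835812677452
75,0.025034275870396083
76,0.02744610034359496
77,0.030091397276844956
78,0.03299201584300726
79,0.036171693279076544
80,0.03965618489415257
81,0.04347339563918862
82,0.047653511256866454
83,0.052229126462973285
84,0.05723536693382214
85,0.06271000107262192
86,0.06869353658600974
87,0.0752292958054297
88,0.08236346242345394
89,0.09014509087240197
90,0.09862606794694084
91,0.10786101446713647
92,0.11790711280911759
93,0.1288238440294539
94,0.1406726161320394
95,0.15351626285890263
96,0.16741839035497652
97,0.18244254733788368
98,0.19865119323569747
99,0.2161044384513492
100,0.2348585318708606
101,0.2549640734483761
102,0.2764639347684108
103,0.2993908785941367
104,0.32376488032521644
105,0.349590170810378
106,0.3768520418542982
107,0.40551348364644124
108,0.43551175753846305
109,0.4667550479041759
110,1.0
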