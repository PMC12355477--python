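# Synthetic life table (Gompertz-Makeham, UK-2020-like scale); not an official national life table.
age,sex,qx
15,male,0.000427197
15,female,0.000216526
16,male,0.000439454
16,female,0.000223156
17,male,0.000452893
17,female,0.000230446
18,male,0.000467626
18,female,0.000238463
19,male,0.000483779
19,female,0.00024728
20,male,0.000501489
20,female,0.000256974
21,male,0.000520906
21,female,0.000267635
22,male,0.000542193
22,female,0.000279359
23,male,0.000565532
23,female,0.00029225
24,male,0.00059112
24,female,0.000306427
25,male,0.000619174
25,female,0.000322016
26,male,0.000649931
26,female,0.000339159
27,male,0.000683652
27,female,0.000358011
28,male,0.000720623
28,female,0.000378741
29,male,0.000761156
29,female,0.000401537
30,male,0.000805595
30,female,0.000426605
31,male,0.000854317
31,female,0.000454171
32,male,0.000907733
32,female,0.000484484
33,male,0.000966297
33,female,0.000517818
34,male,0.0010305
34,female,0.000554475
35,male,0.0011009
35,female,0.000594784
36,male,0.00117808
36,female,0.000639111
37,male,0.00126269
37,female,0.000687855
38,male,0.00135546
38,female,0.000741457
39,male,0.00145717
39,female,0.000800401
40,male,0.00156868
40,female,0.000865219
41,male,0.00169094
41,female,0.000936497
42,male,0.00182498
42,female,0.00101488
43,male,0.00197193
43,female,0.00110107
44,male,0.00213305
44,female,0.00119585
45,male,0.00230969
45,female,0.00130008
46,male,0.00250335
46,female,0.0014147
47,male,0.00271568
47,female,0.00154074
48,male,0.00294847
48,female,0.00167934
49,male,0.00320369
49,female,0.00183175
50,male,0.0034835
50,female,0.00199935
51,male,0.00379028
51,female,0.00218365
52,male,0.00412662
52,female,0.00238632
53,male,0.00449537
53,female,0.00260919
54,male,0.00489965
54,female,0.00285427
55,male,0.0053429
55,female,0.00312378
56,male,0.00582885
56,female,0.00342014
57,male,0.00636164
57,female,0.00374604
58,male,0.00694577
58,female,0.00410442
59,male,0.00758619
59,female,0.00449851
60,male,0.00828832
60,female,0.00493188
61,male,0.00905811
61,female,0.00540843
62,male,0.00990209
62,female,0.00593248
63,male,0.0108274
63,female,0.00650876
64,male,0.0118419
64,female,0.00714247
65,male,0.0129541
65,female,0.00783933
66,male,0.0141735
66,female,0.00860564
67,male,0.0155104
67,female,0.00944832
68,male,0.0169762
68,female,0.010375
69,male,0.0185832
69,female,0.011394
70,male,0.020345
70,female,0.0125145
71,male,0.0222767
71,female,0.0137468
72,male,0.0243944
72,female,0.0151018
73,male,0.0267163
73,female,0.0165919
74,male,0.0292619
74,female,0.0182305
75,male,0.0320528
75,female,0.0200324
76,male,0.0351126
76,female,0.0220138
77,male,0.0384674
77,female,0.0241927
78,male,0.0421453
78,female,0.0265888
79,male,0.0461778
79,female,0.0292237
80,male,0.0505988
80,female,0.0321211
81,male,0.0554458
81,female,0.0353073
82,male,0.0607599
82,female,0.0388111
83,male,0.0665861
83,female,0.042664
84,male,0.0729738
84,female,0.0469009
85,male,0.079977
85,female,0.05156
86,male,0.087655
86,female,0.0566835
87,male,0.096073
87,female,0.0623176
88,male,0.105302
88,female,0.0685131
89,male,0.115421
89,female,0.0753261
90,male,0.126514
90,female,0.0828181
91,male,0.138677
91,female,0.0910567
92,male,0.152011
92,female,0.100116
93,male,0.166631
93,female,0.110079
94,male,0.18266
94,female,0.121034
95,male,0.200233
95,female,0.133081
96,male,0.219499
96,female,0.146329
97,male,0.240622
97,female,0.160897
98,male,0.263781
98,female,0.176917
99,male,0.289171
99,female,0.194534
100,male,1
100,female,1
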