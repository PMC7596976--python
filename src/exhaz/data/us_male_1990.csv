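age,year,rate
0,1990,0.0104440955062308
1,1990,0.000780285131064485
2,1990,0.000540132542960525
3,1990,0.000420077873453868
4,1990,0.000350052638555809
5,1990,0.000310040420144751
6,1990,0.00028003230696874
7,1990,0.000260027398456007
8,1990,0.000230020786053344
9,1990,0.000200015074042749
10,1990,0.000170010262370077
11,1990,0.000170010262370077
12,1990,0.000250025094274863
13,1990,0.000420077873453868
14,1990,0.000640189112354177
15,1990,0.000890374345197049
16,1990,0.00112060005570097
17,1990,0.00130081367935444
18,1990,0.00142097414084762
19,1990,0.00148105978661267
20,1990,0.00155116427008782
21,1990,0.00161125773934783
22,1990,0.00167135482013891
23,1990,0.00170140471499437
24,1990,0.00173145551289529
25,1990,0.00174147264621507
26,1990,0.00176150721389606
27,1990,0.00180157755347963
28,1990,0.00187170451163054
29,1990,0.00196187497046097
30,1990,0.00205205356093676
31,1990,0.00215226153369752
32,1990,0.00224245729579724
33,1990,0.00234268435177342
34,1990,0.00245294571738317
35,1990,0.00257324471112334
36,1990,0.00270358495456351
37,1990,0.00282391410628822
38,1990,0.00293422854995297
39,1990,0.00304455516453686
40,1990,0.00315489395272557
41,1990,0.0032853100373364
42,1990,0.00344584549431038
43,1990,0.00365658740060749
44,1990,0.0039075285445736
45,1990,0.00421878304547387
46,1990,0.00458036150821091
47,1990,0.00497221910479294
48,1990,0.00538433759995413
49,1990,0.00581674198968834
50,1990,0.00631977301762235
51,1990,0.00691367528241343
52,1990,0.00757845878074485
53,1990,0.00831426473009087
54,1990,0.00913134112471104
55,1990,0.00999958567590039
56,1990,0.0109494602777125
57,1990,0.0120419205946403
58,1990,0.0132875669044879
59,1990,0.0146565281882494
60,1990,0.016037527512819
61,1990,0.0174509635999502
62,1990,0.0189479253580071
63,1990,0.0206002380920529
64,1990,0.0223882168044434
65,1990,0.0242613575059985
66,1990,0.0261996029111354
67,1990,0.0283267626466094
68,1990,0.0307677755147493
69,1990,0.0335662977279353
70,1990,0.0367356959020167
71,1990,0.0402482501399176
72,1990,0.0440553006186153
73,1990,0.0480342654135292
74,1990,0.052123934888843
75,1990,0.0564843071421234
76,1990,0.0612676948017756
77,1990,0.0664587290731642
78,1990,0.0722356350673423
79,1990,0.0787815595301467
80,1990,0.0864603062845357
81,1990,0.0951658448786382
82,1990,0.104369543599944
83,1990,0.113367492653962
84,1990,0.122130726788144
85,1990,0.132134822054927
86,1990,0.144143993197484
87,1990,0.157351933425633
88,1990,0.171614804855061
89,1990,0.18702400913534
90,1990,0.20407146001821
91,1990,0.223113053838985
92,1990,0.243289244570495
93,1990,0.263412329503281
94,1990,0.282594702773658
95,1990,0.301151727539648
96,1990,0.322072362904028
97,1990,0.341679394718226
98,1990,0.362253024435012
99,1990,0.384330356107348
100,1990,0.408033374664752
101,1990,0.433560732246358
102,1990,0.46107217046998
103,1990,0.490798506831024
104,1990,0.52298653764822
105,1990,0.557938424203104
106,1990,0.59600578349321
107,1990,0.637602159444161
108,1990,0.683239421528835
109,1990,0.7334928725578
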