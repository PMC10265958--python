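index,name,formula,mz,mass_error_ppm,rt_min,mzcloud_id,hmdb_id
1,"N,N-dimethylsphingosine",C20H41NO2,327.3135,-0.9,22.302,4434,HMDB0013645
2,Glycerophospho-n-palmitoyl ethanolamine,C21H44NO7P,453.2856,0.2,16.403,2955,
3,DL-tryptophan,C11H12N2O2,204.0899,0.2,8.241,415,HMDB0013609
4,L-(+)-valine,C5H11NO2,117.0789,-0.5,0.880,2570,HMDB0000883
5,Indoleacrylic acid,C11H9NO2,187.0633,0.0,8.240,449,HMDB0000734
6,Taurine,C2H7NO3S,125.0146,-0.2,0.852,654,HMDB0000251
7,Medroxyprogesterone,C22H32O3,344.2355,1.0,17.385,1321,HMDB0001939
8,4-Coumaric acid,C9H8O3,164.0474,0.2,1.086,539,HMDB0002035
9,L-tyrosine,C9H11NO3,181.0739,0.2,1.078,2255,HMDB0000158
10,18-HETE,C20H32O3,320.2354,0.9,17.521,4720,HMDB0006245
11,Cholic acid,C24H40O5,408.2882,1.5,13.096,344,HMDB0000619
12,L-(-)-methionine,C5H11NO2S,149.0511,0.1,1.080,1544,HMDB0000696
13,13S-hydroxyoctadecadienoic acid,C18H32O3,296.2354,0.8,16.744,9778,HMDB0004667
14,Uridine,C9H12N2O6,244.0698,1.0,1.853,1408,HMDB0000296
15,alpha-Eleostearic acid,C18H30O2,278.2244,-0.7,16.753,6594,HMDB0248208
16,Uric acid,C5H4N4O3,168.0283,-0.1,1.076,753,HMDB0000289
17,alpha-Linolenoyl ethanolamide,C20H35NO2,321.2666,-0.7,17.587,4417,HMDB0013624
18,2-Arachidonoylglycerol,C23H38O4,378.2768,-0.6,20.076,4740,HMDB0004666
19,Leucine,C6H13NO2,131.0947,0.4,0.357,6,HMDB0000687
20,"3a,7a-dihydroxycholanoic acid",C24H40O4,392.2933,1.5,15.084,9830,HMDB0000384
21,Glycochenodeoxycholic acid,C26H43NO5,449.3145,0.9,13.513,9839,HMDB0000637
22,Juniperic acid,C16H32O3,272.2356,1.5,20.262,2551,HMDB0006294
23,15-HETE,C20H32O3,320.2354,0.9,17.069,8581,HMDB0003876
24,Uracil,C4H4N2O2,112.0272,-0.6,1.845,2531,HMDB0000300
25,Deoxycholic acid,C24H40O4,392.2933,-0.9,15.400,388,HMDB0000626
26,Dodecanedioic acid,C12H22O4,230.1518,0.1,11.170,1182,HMDB0000623
27,Bilirubin,C33H36N4O6,584.2630,-0.8,25.613,334,HMDB0000054
28,Eicosapentaenoic acid,C20H30O2,302.2244,-0.5,20.345,348,HMDB0001999
29,DL-phenylalanine,C9H11NO2,165.0790,0.1,1.153,8,HMDB0250791
30,Desaminotyrosine,C9H10O3,166.0630,0.0,9.922,183,HMDB0002199
31,9-HpODE,C18H32O4,312.2299,-0.6,12.722,8563,HMDB0242602
32,(-)-Prostaglandin E1,C20H34O5,354.2412,1.6,13.359,1356,HMDB0001442
33,Arachidonic acid,C20H32O2,304.2400,-0.8,17.734,2742,HMDB0001043
34,Hexadecanedioic acid,C16H30O4,286.2148,1.2,13.304,2712,HMDB0000672
35,Ecgonine,C9H15NO3,185.1052,0.1,9.746,2066,HMDB0006548
36,"(11E,15Z)-9,10,13-trihydroxyoctadeca-11,15-dienoic acid",C18H32O5,328.2254,1.4,11.572,1416,
37,NP-011548,C18H34O3,298.2506,-0.8,19.620,6496,
38,Muscone,C16H30O,238.2295,-0.6,22.893,6153,HMDB0034181
39,D-sphingosine,C18H37NO2,299.2821,-1.1,15.563,418,HMDB0000252
40,N-acetylvaline,C7H13NO3,159.0896,0.2,9.480,1365,HMDB0011757
41,Sphinganine,C18H39NO2,301.2979,-0.6,11.921,391,HMDB0000269
42,(9Z)-9-octadecenamide,C18H35NO,281.2718,-0.4,24.440,530,HMDB0002117
43,Vitamin C,C6H8O6,176.0321,0.2,11.161,325,HMDB0000044
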