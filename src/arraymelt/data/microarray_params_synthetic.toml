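[global]
name = "microarray-synthetic-v1"
m_value = 0.173
log10_effective_probe_conc = -2.0
dg_init = 1.96
gas_constant = 0.00199
temperature = 315.15
bulge_alpha = 0.238
sm_linear = [0.354, 0.487]
tandem_linear = [0.198, 1.167]

[nearest_neighbors]
"AA/TT" = -0.2960
"AC/TG" = -0.4060
"AG/TC" = -0.3660
"AT/TA" = -0.2660
"CA/GT" = -0.4085
"CC/GG" = -0.5060
"CG/GC" = -0.5885
"GA/CT" = -0.3710
"GC/CG" = -0.6060
"TA/AT" = -0.1910

[single_mismatch_loops]
"AAA/TAT" = 1.1423
"AAA/TCT" = 1.6370
"AAA/TGT" = 0.7444
"AAC/TAG" = 0.8696
"AAC/TCG" = 1.0719
"AAC/TGG" = 0.2372
"AAG/TAC" = 0.8628
"AAG/TCC" = 1.2380
"AAG/TGC" = 0.4528
"AAT/TAA" = 1.1499
"AAT/TCA" = 1.5242
"AAT/TGA" = 0.6594
"ACA/TAT" = 1.5769
"ACA/TCT" = 1.8260
"ACA/TTT" = 1.3992
"ACC/TAG" = 1.2519
"ACC/TCG" = 1.3521
"ACC/TTG" = 1.1256
"ACG/TAC" = 1.0574
"ACG/TCC" = 1.5421
"ACG/TTC" = 1.2415
"ACT/TCA" = 1.8371
"ACT/TTA" = 1.2940
"AGA/TAT" = 0.5668
"AGA/TGT" = 0.1661
"AGA/TTT" = 0.5325
"AGC/TAG" = 0.3267
"AGC/TGG" = 0.0170
"AGC/TTG" = 0.2380
"AGG/TAC" = 0.4430
"AGG/TGC" = -0.0649
"AGG/TTC" = 0.1641
"AGT/TGA" = 0.2154
"AGT/TTA" = 0.5899
"ATA/TCT" = 1.3287
"ATA/TGT" = 0.5232
"ATA/TTT" = 1.3448
"ATC/TCG" = 1.2481
"ATC/TGG" = 0.1209
"ATC/TTG" = 0.8324
"ATG/TCC" = 1.1357
"ATG/TGC" = 0.1529
"ATG/TTC" = 0.8025
"ATT/TTA" = 1.3457
"CAA/GAT" = 0.9242
"CAA/GCT" = 1.2137
"CAA/GGT" = 0.4389
"CAC/GAG" = 0.5365
"CAC/GCG" = 0.8185
"CAC/GGG" = 0.1934
"CAG/GAC" = 0.4085
"CAG/GCC" = 0.9805
"CAG/GGC" = 0.0362
"CCA/GAT" = 1.2965
"CCA/GCT" = 1.5109
"CCA/GTT" = 1.0952
"CCC/GAG" = 0.8204
"CCC/GCG" = 1.1943
"CCC/GTG" = 0.7739
"CCG/GCC" = 1.2312
"CCG/GTC" = 0.8349
"CGA/GAT" = 0.3078
"CGA/GGT" = -0.0660
"CGA/GTT" = 0.1374
"CGC/GAG" = 0.0038
"CGC/GGG" = -0.2993
"CGC/GTG" = -0.1502
"CGG/GGC" = -0.2018
"CGG/GTC" = -0.0284
"CTA/GCT" = 1.1285
"CTA/GGT" = 0.3321
"CTA/GTT" = 0.8361
"CTC/GCG" = 0.8834
"CTC/GGG" = -0.2120
"CTC/GTG" = 0.6568
"CTG/GTC" = 0.5882
"GAA/CAT" = 0.8812
"GAA/CCT" = 1.1211
"GAA/CGT" = 0.4160
"GAC/CAG" = 0.6350
"GAC/CCG" = 0.9984
"GAC/CGG" = -0.0884
"GCA/CAT" = 1.0821
"GCA/CCT" = 1.5380
"GCA/CTT" = 1.1600
"GCC/CCG" = 1.1947
"GCC/CTG" = 0.8161
"GGA/CAT" = 0.2831
"GGA/CGT" = -0.0821
"GGA/CTT" = 0.2541
"GGC/CGG" = -0.2671
"GGC/CTG" = -0.1813
"GTA/CCT" = 1.0017
"GTA/CGT" = 0.2972
"GTA/CTT" = 0.9240
"GTC/CTG" = 0.5016
"TAA/AAT" = 1.0230
"TAA/ACT" = 1.6468
"TAA/AGT" = 0.6029
"TCA/ACT" = 1.8487
"TCA/ATT" = 1.4854
"TGA/AGT" = 0.4172
"TGA/ATT" = 0.5376
"TTA/ATT" = 1.2940

[bulge]
"A.A.A" = 3.8780
"A.A.C" = 3.3342
"A.A.G" = 3.6749
"A.A.T" = 3.5115
"A.C.A" = 3.9552
"A.C.C" = 3.7288
"A.C.G" = 3.6266
"A.C.T" = 3.6314
"A.G.A" = 3.5909
"A.G.C" = 3.2037
"A.G.G" = 3.4778
"A.G.T" = 3.5474
"A.T.A" = 3.8282
"A.T.C" = 3.7445
"A.T.G" = 3.3621
"A.T.T" = 3.8671
"C.A.A" = 3.3247
"C.A.C" = 3.2721
"C.A.G" = 3.4225
"C.A.T" = 3.4800
"C.C.A" = 3.4019
"C.C.C" = 3.2115
"C.C.G" = 3.3132
"C.C.T" = 3.4869
"C.G.A" = 3.5178
"C.G.C" = 3.0103
"C.G.G" = 3.1516
"C.G.T" = 3.4716
"C.T.A" = 3.6843
"C.T.C" = 3.5400
"C.T.G" = 3.3074
"C.T.T" = 3.6057
"G.A.A" = 3.3738
"G.A.C" = 3.1206
"G.A.G" = 3.3244
"G.A.T" = 3.6922
"G.C.A" = 3.5907
"G.C.C" = 3.4059
"G.C.G" = 3.3223
"G.C.T" = 3.4550
"G.G.A" = 3.4831
"G.G.C" = 3.3296
"G.G.G" = 3.1548
"G.G.T" = 3.2724
"G.T.A" = 3.4081
"G.T.C" = 3.3900
"G.T.G" = 3.1705
"G.T.T" = 3.4740
"T.A.A" = 3.8031
"T.A.C" = 3.5697
"T.A.G" = 3.6704
"T.A.T" = 3.5733
"T.C.A" = 3.7558
"T.C.C" = 3.5381
"T.C.G" = 3.4045
"T.C.T" = 3.8895
"T.G.A" = 3.7206
"T.G.C" = 3.3013
"T.G.G" = 3.3300
"T.G.T" = 3.6894
"T.T.A" = 3.8495
"T.T.C" = 3.5058
"T.T.G" = 3.3509
"T.T.T" = 3.9479

[tandem]
"AT:GA" = 0.5500
"AT:GG" = 0.3500
"AT:GT" = 0.4500
"AT:other" = 1.0000
"GC:GA" = 0.2500
"GC:GG" = 0.0500
"GC:GT" = 0.1500
"GC:other" = 0.7000

[single_mismatch_loops_sln]
"AAA/TAT" = 1.8511
"AAA/TCT" = 3.2486
"AAA/TGT" = 0.7271
"AAC/TAG" = 1.0808
"AAC/TCG" = 1.6523
"AAC/TGG" = -0.7056
"AAG/TAC" = 1.0616
"AAG/TCC" = 2.1215
"AAG/TGC" = -0.0966
"AAT/TAA" = 1.8726
"AAT/TCA" = 2.9299
"AAT/TGA" = 0.4870
"ACA/TAT" = 3.0788
"ACA/TCT" = 3.7825
"ACA/TTT" = 2.5768
"ACC/TAG" = 2.1607
"ACC/TCG" = 2.4438
"ACC/TTG" = 1.8040
"ACG/TAC" = 1.6113
"ACG/TCC" = 2.9805
"ACG/TTC" = 2.1314
"ACT/TCA" = 3.8138
"ACT/TTA" = 2.2797
"AGA/TAT" = 0.2254
"AGA/TGT" = -0.9065
"AGA/TTT" = 0.1285
"AGC/TAG" = -0.4528
"AGC/TGG" = -1.3277
"AGC/TTG" = -0.7034
"AGG/TAC" = -0.1243
"AGG/TGC" = -1.5590
"AGG/TTC" = -0.9121
"AGT/TGA" = -0.7672
"AGT/TTA" = 0.2907
"ATA/TCT" = 2.3777
"ATA/TGT" = 0.1023
"ATA/TTT" = 2.4232
"ATC/TCG" = 2.1500
"ATC/TGG" = -1.0342
"ATC/TTG" = 0.9757
"ATG/TCC" = 1.8325
"ATG/TGC" = -0.9438
"ATG/TTC" = 0.8912
"ATT/TTA" = 2.4257
"CAA/GAT" = 1.2350
"CAA/GCT" = 2.0528
"CAA/GGT" = -0.1359
"CAC/GAG" = 0.1398
"CAC/GCG" = 0.9364
"CAC/GGG" = -0.8294
"CAG/GAC" = -0.2218
"CAG/GCC" = 1.3941
"CAG/GGC" = -1.2734
"CCA/GAT" = 2.2867
"CCA/GCT" = 2.8924
"CCA/GTT" = 1.7181
"CCC/GAG" = 0.9418
"CCC/GCG" = 1.9980
"CCC/GTG" = 0.8105
"CCG/GCC" = 2.1023
"CCG/GTC" = 0.9828
"CGA/GAT" = -0.5062
"CGA/GGT" = -1.5621
"CGA/GTT" = -0.9876
"CGC/GAG" = -1.3650
"CGC/GGG" = -2.2212
"CGC/GTG" = -1.8000
"CGG/GGC" = -1.9458
"CGG/GTC" = -1.4559
"CTA/GCT" = 1.8121
"CTA/GGT" = -0.4376
"CTA/GTT" = 0.9862
"CTC/GCG" = 1.1198
"CTC/GGG" = -1.9746
"CTC/GTG" = 0.4797
"CTG/GTC" = 0.2859
"GAA/CAT" = 1.1136
"GAA/CCT" = 1.7912
"GAA/CGT" = -0.2006
"GAC/CAG" = 0.4181
"GAC/CCG" = 1.4446
"GAC/CGG" = -1.6254
"GCA/CAT" = 1.6811
"GCA/CCT" = 2.9689
"GCA/CTT" = 1.9011
"GCC/CCG" = 1.9992
"GCC/CTG" = 0.9297
"GGA/CAT" = -0.5760
"GGA/CGT" = -1.6076
"GGA/CTT" = -0.6579
"GGC/CGG" = -2.1302
"GGC/CTG" = -1.8879
"GTA/CCT" = 1.4540
"GTA/CGT" = -0.5362
"GTA/CTT" = 1.2345
"GTC/CTG" = 0.0412
"TAA/AAT" = 1.5141
"TAA/ACT" = 3.2763
"TAA/AGT" = 0.3274
"TCA/ACT" = 3.8466
"TCA/ATT" = 2.8203
"TGA/AGT" = -0.1972
"TGA/ATT" = 0.1429
"TTA/ATT" = 2.2797
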