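genotype,root_id,root_type,zone,slope_per_mm,correlation,correlation_ns,n_cells,end_um
wild-type,A10,A,DZ,0.8,0.12,1,132,855
wild-type,A10,A,EZ,59.5,0.88,0,67,1494
wild-type,A10,A,MZ,49.6,0.78,0,68,2990
wild-type,A31,A,DZ,-6,-0.42,0,78,676
wild-type,A31,A,EZ,50.5,0.9,0,95,1368
wild-type,A31,A,MZ,65.9,0.73,0,70,3126
wild-type,A9,A,DZ,-5.3,-0.35,0,94,587
wild-type,A9,A,EZ,42.4,0.91,0,61,1219
wild-type,A9,A,MZ,43.1,0.76,0,67,3557
wild-type,A8,A,DZ,-3.2,-0.36,1,17,553
wild-type,A8,A,EZ,59.2,0.83,0,34,1100
wild-type,A8,A,MZ,49.4,0.77,0,37,2459
wild-type,A13,A,DZ,-3.6,-0.24,0,109,510
wild-type,A13,A,EZ,90.9,0.87,0,76,973
wild-type,A13,A,MZ,30.1,0.35,0,53,2582
wild-type,B33,B,DZ,-0.2,-0.01,1,103,439
wild-type,B33,B,EZ,201.8,0.82,0,36,672
wild-type,B33,B,MZ,15.1,0.21,1,59,2198
wild-type,B32,B,DZ,-16,-0.53,0,110,411
wild-type,B32,B,EZ,116.3,0.81,0,48,716
wild-type,B32,B,MZ,35.2,0.44,0,39,1852
wild-type,B19,B,DZ,11.6,0.42,0,30,366
wild-type,B19,B,EZ,118.8,0.85,0,31,600
wild-type,B19,B,MZ,21.2,0.36,0,36,2283
wild-type,A11,A,DZ,-6.3,-0.25,1,55,328
wild-type,A11,A,EZ,83,0.9,0,77,655
wild-type,A11,A,MZ,74.6,0.72,0,50,1898
wild-type,A12,A,DZ,1.3,0.05,1,49,320
wild-type,A12,A,EZ,102.5,0.91,0,44,722
wild-type,A12,A,MZ,13.3,0.33,0,77,2967
wild-type,B34,B,DZ,-9.6,-0.4,0,27,278
wild-type,B34,B,EZ,140.1,0.72,0,57,461
wild-type,B34,B,MZ,27.6,0.55,0,68,2182
wild-type,B20,B,DZ,1,0.02,1,48,232
wild-type,B20,B,EZ,201.4,0.88,0,52,574
wild-type,B20,B,MZ,15.9,0.44,0,34,2775
wild-type,B35,B,DZ,-22.1,-0.32,0,44,215
wild-type,B35,B,EZ,183.3,0.76,0,44,388
wild-type,B35,B,MZ,3.2,0.09,1,79,2771
wild-type,C25,C,EZ,159,0.75,0,18,144
wild-type,C25,C,MZ,30.6,0.82,0,110,1961
wild-type,C28,C,EZ,108.6,0.53,0,40,115
wild-type,C28,C,MZ,9.4,0.26,0,111,1424
wild-type,C26,C,MZ,28.1,0.82,0,133,2115
wild-type,C27,C,MZ,22.7,0.72,0,136,2172
wild-type,C30,C,MZ,27.6,0.69,0,170,2214
rtcs,A3,A,DZ,11.2,0.34,0,67,617
rtcs,A3,A,EZ,83.4,0.81,0,29,1385
rtcs,A3,A,MZ,7.7,0.05,1,16,2277
rtcs,A1,A,DZ,8.3,0.36,0,92,535
rtcs,A1,A,EZ,59.6,0.88,0,60,1185
rtcs,A1,A,MZ,24.5,0.34,0,62,3407
rtcs,A'36,A',DZ,2.3,0.15,1,116,506
rtcs,A'36,A',EZ,92.2,0.93,0,39,1146
rtcs,A'36,A',MZ,25.5,0.3,1,22,1998
rtcs,A2,A,DZ,27.9,0.64,0,68,323
rtcs,A2,A,EZ,157.5,0.86,0,29,744
rtcs,A2,A,MZ,10.1,0.17,1,35,2257
rtcs,A'37,A',DZ,20.4,0.63,0,42,313
rtcs,A'37,A',EZ,82.2,0.84,0,51,707
rtcs,A'37,A',MZ,31.2,0.47,0,40,1514
rtcs,A'38,A',DZ,9.7,0.51,0,46,272
rtcs,A'38,A',EZ,111.7,0.82,0,41,505
rtcs,A'38,A',MZ,28.7,0.49,0,47,1621
rtcs,A'39,A',EZ,66,0.84,0,37,980
rtcs,A'39,A',MZ,23.5,0.23,1,27,1844
rtcs,B15,B,EZ,139.5,0.96,0,30,520
rtcs,B15,B,MZ,-9.5,-0.18,1,22,1493
rum-1,A5,A,DZ,-3.3,-0.28,0,157,787
rum-1,A5,A,EZ,65,0.96,0,73,2360
rum-1,A5,A,MZ,21.1,0.22,1,29,4090
rum-1,A7,A,DZ,3,0.15,1,71,456
rum-1,A7,A,EZ,62,0.85,0,55,1123
rum-1,A7,A,MZ,41,0.58,0,13,2109
rum-1,A'41,A',DZ,-6,-0.17,1,75,452
rum-1,A'41,A',EZ,75,0.84,0,61,1246
rum-1,A'41,A',MZ,16.9,0.18,1,16,2329
rum-1,A4,A,DZ,0,0,1,101,399
rum-1,A4,A,EZ,42.3,0.8,0,87,1068
rum-1,A4,A,MZ,6.5,0.08,1,46,1870
rum-1,A'40,A',DZ,19.5,0.43,0,122,385
rum-1,A'40,A',EZ,139.9,0.71,0,41,689
rum-1,A'40,A',MZ,13,0.2,1,52,2235
rum-1,A6,A,DZ,-14.7,-0.57,0,68,371
rum-1,A6,A,EZ,43.1,0.83,0,67,958
rum-1,A6,A,MZ,73.7,0.64,0,31,2139
rum-1,A'42,A',DZ,26.7,0.57,0,73,295
rum-1,A'42,A',EZ,145.3,0.93,0,33,627
rum-1,A'42,A',MZ,2.4,0.06,1,55,2325
rum-1,C22,C,EZ,11.6,0.61,0,73,1510
rum-1,C22,C,MZ,14.4,0.34,0,38,2820
rum-1,C24,C,EZ,9.8,0.38,0,62,540
rum-1,C24,C,MZ,13.5,0.67,0,81,3247
rum-1,C23,C,EZ,85.2,0.85,0,39,732
rum-1,C23,C,MZ,22.6,0.64,0,48,2008
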