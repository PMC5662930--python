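genotype,root_id,root_type,zone,pred_start_um,pred_end_um,end_um,ci_rootward_lo,ci_rootward_hi,ci_shootward_lo,ci_shootward_hi
wild-type,A10,A,DZ,5.4,6,855,5.5,6.5,5,9.7
wild-type,A10,A,EZ,7.3,45.4,1494,41.8,48.9,45.7,61
wild-type,A10,A,MZ,53.3,127.6,2990,,,,
wild-type,A31,A,DZ,9.3,5.7,676,4.8,6.7,4.2,8
wild-type,A31,A,EZ,6.1,41,1368,38.9,43.2,47.7,70.9
wild-type,A31,A,MZ,59.3,175.2,3126,,,,
wild-type,A9,A,DZ,7.8,5.1,587,4.2,6,5,8.3
wild-type,A9,A,EZ,6.7,33.5,1219,31.5,35.4,40.2,65
wild-type,A9,A,MZ,52.6,153.4,3557,,,,
wild-type,A8,A,DZ,7.7,6.7,553,6.1,7.2,2.4,12.8
wild-type,A8,A,EZ,7.6,40,1100,36.4,43.6,42.7,60.7
wild-type,A8,A,MZ,51.7,118.8,2459,,,,
wild-type,A13,A,DZ,7.3,5.4,510,4.7,6.2,3.9,9.2
wild-type,A13,A,EZ,6.5,48.6,973,45.1,52.2,69.2,108
wild-type,A13,A,MZ,88.6,137,2582,,,,
wild-type,B33,B,DZ,6.4,6.3,439,5.5,7,4.4,14.8
wild-type,B33,B,EZ,9.6,56.6,672,49.2,64,68.6,99.3
wild-type,B33,B,MZ,83.9,107.1,2198,,,,
wild-type,B32,B,DZ,9.3,3.6,411,2.5,4.7,6.1,13.8
wild-type,B32,B,EZ,10,45.5,716,40.7,50.2,60.6,87.1
wild-type,B32,B,MZ,73.8,113.8,1852,,,,
wild-type,B19,B,DZ,6.5,8.9,366,7.8,9.9,7.7,14.6
wild-type,B19,B,EZ,11.2,39,600,34.9,43,66.6,107.8
wild-type,B19,B,MZ,87.2,122.9,2283,,,,
wild-type,A11,A,DZ,7.3,5.5,328,4.3,6.7,3.6,6.6
wild-type,A11,A,EZ,5.1,32.3,655,30.3,34.2,44.1,65.7
wild-type,A11,A,MZ,54.9,147.6,1898,,,,
wild-type,A12,A,DZ,5.9,6.2,320,5.3,7.1,4.5,9.7
wild-type,A12,A,EZ,7.1,48.3,722,44.2,52.4,59,79.2
wild-type,A12,A,MZ,69.1,98.9,2967,,,,
wild-type,B34,B,DZ,6.4,4.9,278,4.1,5.7,1.4,8.3
wild-type,B34,B,EZ,4.8,30.5,461,26.5,34.5,52.7,72.2
wild-type,B34,B,MZ,62.4,109.9,2182,,,,
wild-type,B20,B,DZ,11.3,11.5,232,10,13,6.5,16.6
wild-type,B20,B,EZ,11.6,80.4,574,73.5,87.4,88.5,115.9
wild-type,B20,B,MZ,102.2,137.2,2775,,,,
wild-type,B35,B,DZ,9.2,5.1,215,3.3,7,4.8,13.2
wild-type,B35,B,EZ,9,40.7,388,35.5,45.9,55.1,71.9
wild-type,B35,B,MZ,63.5,71,2771,,,,
wild-type,C25,C,EZ,5.2,25.7,144,18.2,33.1,20.9,28.4
wild-type,C25,C,MZ,24.6,80.3,1961,,,,
wild-type,C28,C,EZ,6.3,16.7,115,13.9,19.5,25,33.4
wild-type,C28,C,MZ,29.2,41.4,1424,,,,
wild-type,C26,C,MZ,20.3,79.2,2115,,,,
wild-type,C27,C,MZ,28.5,77.2,2172,,,,
wild-type,C30,C,MZ,28.7,89,2214,,,,
rtcs,A3,A,DZ,11.9,18.3,617,15.7,20.9,17.7,34.4
rtcs,A3,A,EZ,26,90.1,1385,77.7,102.4,63.7,139.4
rtcs,A3,A,MZ,101.5,108.4,2277,,,,
rtcs,A1,A,DZ,7.6,12,535,10.5,13.6,13.3,18.5
rtcs,A1,A,EZ,15.9,54.6,1185,50.8,58.4,57.1,97.3
rtcs,A1,A,MZ,77.2,131.6,3407,,,,
rtcs,A'36,A',DZ,7.5,8.6,506,7.8,9.4,7.1,13.8
rtcs,A'36,A',EZ,10.4,69.4,1146,63.8,75,51.1,86.2
rtcs,A'36,A',MZ,68.6,90.3,1998,,,,
rtcs,A2,A,DZ,5.6,14.6,323,13,16.2,10.4,24.7
rtcs,A2,A,EZ,17.5,83.8,744,73.4,94.3,64.3,99.5
rtcs,A2,A,MZ,81.9,97.2,2257,,,,
rtcs,A'37,A',DZ,5.6,9.1,313,8.3,9.9,7.1,12.8
rtcs,A'37,A',EZ,10,42.4,707,38.2,46.5,41.6,59.2
rtcs,A'37,A',MZ,50.4,75.5,1514,,,,
rtcs,A'38,A',DZ,6.3,9,272,8.3,9.6,2.7,6.8
rtcs,A'38,A',EZ,4.8,30.8,505,26.3,35.3,34.2,51.7
rtcs,A'38,A',MZ,42.9,75,1621,,,,
rtcs,A'39,A',EZ,11.1,59.7,980,53.1,66.3,34.3,74.4
rtcs,A'39,A',MZ,54.4,74.7,1844,,,,
rtcs,B15,B,EZ,8.9,79.3,520,73.7,85,54.9,82
rtcs,B15,B,MZ,68.5,59.2,1493,,,,
rum-1,A5,A,DZ,10.2,7.7,787,6.9,8.5,6.6,12.9
rum-1,A5,A,EZ,9.8,112,2360,106.5,117.6,69,140
rum-1,A5,A,MZ,104.5,140.9,4090,,,,
rum-1,A7,A,DZ,6.7,7.8,456,6.9,8.6,4.3,10.5
rum-1,A7,A,EZ,7.4,48.8,1123,43.7,53.8,51.7,91.7
rum-1,A7,A,MZ,71.7,112.2,2109,,,,
rum-1,A'41,A',DZ,13.7,11,452,9.1,12.9,8.4,16.6
rum-1,A'41,A',EZ,12.5,72.1,1246,64.9,79.2,27.6,91.6
rum-1,A'41,A',MZ,59.6,78,2329,,,,
rum-1,A4,A,DZ,8.9,8.9,399,8.1,9.8,8.7,13.1
rum-1,A4,A,EZ,10.9,39.2,1068,36.1,42.3,38.5,61
rum-1,A4,A,MZ,49.8,55,1870,,,,
rum-1,A'40,A',DZ,9.9,17.4,385,15.7,19.1,12.2,25.4
rum-1,A'40,A',EZ,18.8,61.3,689,52.1,70.6,58.4,86.4
rum-1,A'40,A',MZ,72.4,92.6,2235,,,,
rum-1,A6,A,DZ,12,6.6,371,5.6,7.6,4.4,8.4
rum-1,A6,A,EZ,6.4,31.6,958,28.8,34.5,20.1,59
rum-1,A6,A,MZ,39.5,126.5,2139,,,,
rum-1,A'42,A',DZ,7.3,15.2,295,13.5,16.9,8.9,15.3
rum-1,A'42,A',EZ,12.1,60.3,627,55.4,65.3,51.1,72.1
rum-1,A'42,A',MZ,61.6,65.7,2325,,,,
rum-1,C22,C,EZ,13.2,29.2,1510,26.6,31.9,45.5,65
rum-1,C22,C,MZ,55.2,74.1,2820,,,,
rum-1,C24,C,EZ,15.4,20.7,540,18.7,22.7,19.5,28.4
rum-1,C24,C,MZ,23.9,60.6,3247,,,,
rum-1,C23,C,EZ,8,53.5,732,47.1,59.8,34.1,45.5
rum-1,C23,C,MZ,39.8,68.7,2008,,,,
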