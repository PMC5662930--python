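genotype,root_id,root_type,family,dz_sd,dzez_limit,dzez_lo,dzez_hi,ez_sd,ezmz_limit,ezmz_lo,ezmz_hi,first_hair_um,mz_sd,seg_posterior,seg_supported,model_posterior,model_supported,sh_n_zones
wild-type,A10,A,linear,1.3,855,761,855,5.5,1494,1121,1556,2122,18.2,0.16,1,1,1,3
wild-type,A10,A,variance,1.3,855,766,867,5.5,1494,1188,1561,,18.1,0.17,1,0.54,1,3
wild-type,A31,A,linear,2.2,676,633,763,4.6,1368,1323,1368,1692,29.9,0.1,1,1,1,3
wild-type,A31,A,variance,2.6,988,898,1019,5.8,1368,1323,1370,,29.7,0.1,1,0.95,1,3
wild-type,A9,A,linear,2,587,528,635,3.5,1219,1177,1242,2318,27.8,0.13,1,1,1,3
wild-type,A9,A,variance,2.2,1008,973,1053,7.3,1531,1440,2295,,30.4,0.07,1,0.95,1,3
wild-type,A8,A,linear,0.8,553,532,553,5.4,1100,1001,1100,1862,17,0.13,1,0.29,0,2
wild-type,A8,A,variance,0.7,553,532,553,4.4,1030,980,1100,,15.9,0.16,1,0.98,1,3
wild-type,A13,A,linear,2,510,459,521,6,973,952,973,1267,37.5,0.24,1,0,0,4
wild-type,A13,A,variance,2,511,489,521,6,1013,915,1013,,37.5,0.25,1,0.91,1,3
wild-type,B33,B,linear,1.8,439,387,439,8.1,672,631,672,781,33.4,0.21,1,0,0,4
wild-type,B33,B,variance,1.8,458,427,473,8.4,672,628,672,,33.3,0.21,1,0.98,1,3
wild-type,B32,B,linear,2.2,411,337,411,6.7,716,672,716,929,24.7,0.35,1,0,0,4
wild-type,B32,B,variance,2.2,411,337,517,6.8,719,672,824,,24.9,0.1,1,0.02,0,4
wild-type,B19,B,linear,1.7,366,344,396,4.9,600,578,770,895,32.5,0.17,1,1,1,3
wild-type,B19,B,variance,1.8,415,358,435,5.3,600,568,600,,32.1,0.21,1,0.98,1,3
wild-type,A11,A,linear,1.9,328,255,383,3.6,655,647,655,1165,24.1,0.13,1,0.96,1,3
wild-type,A11,A,variance,2.2,454,277,474,4.6,678,654,678,,24.3,0.1,1,0.98,1,3
wild-type,A12,A,linear,1.7,320,314,320,5.1,722,677,722,756,25.6,0.5,1,1,1,3
wild-type,A12,A,variance,1.7,320,314,363,5.2,729,677,729,,25.6,0.26,1,1,1,3
wild-type,B34,B,linear,1.2,278,274,318,6.3,461,392,461,515,24.6,0.27,1,0.85,1,3
wild-type,B34,B,variance,1.2,278,270,297,4,392,391,474,,22.2,0.17,1,0.13,0,4
wild-type,B20,B,linear,2.7,232,227,253,10.1,574,517,696,586,25.3,0.14,1,1,1,3
wild-type,B20,B,variance,2.7,232,224,253,9.8,591,349,591,,25.7,0.2,1,0.91,1,3
wild-type,B35,B,linear,3,215,171,224,7.2,388,367,446,430,23.2,0.19,1,1,1,3
wild-type,B35,B,variance,3.3,257,207,293,12,1157,388,1157,,29.9,0.02,1,0.72,1,3
wild-type,C25,C,linear,,,,,3.2,144,67,180,121,11.6,0.37,1,0.01,0,1
wild-type,C25,C,variance,,,,,3.1,144,67,722,,11.6,0.44,1,0.9,1,2
wild-type,C28,C,linear,,,,,4.2,115,106,115,166,12.8,0.65,1,1,1,2
wild-type,C28,C,variance,,,,,4.5,139,97,139,,13,0.21,1,1,1,2
wild-type,C26,C,linear,,,,,,,,,101,11.5,1,1,1,1,1
wild-type,C26,C,variance,,,,,,,,,,11.5,1,1,0.27,0,2
wild-type,C27,C,linear,,,,,,,,,93,14,1,1,1,1,1
wild-type,C27,C,variance,,,,,,,,,,14,1,1,0.61,1,1
wild-type,C30,C,linear,,,,,,,,,197,15.9,1,1,1,1,1
wild-type,C30,C,variance,,,,,,,,,,15.9,1,1,0.95,1,1
rtcs,A3,A,linear,4.8,617,548,662,12.9,1385,879,1421,1083,40.1,0.05,0,0,0,2
rtcs,A3,A,variance,4.7,634,553,718,13.1,1385,879,1421,,38.7,0.19,1,0.53,1,3
rtcs,A1,A,linear,3.4,535,321,649,6,1185,1112,1185,1078,43.6,0.14,1,1,1,3
rtcs,A1,A,variance,3.4,583,387,775,6.3,1185,1112,1185,,43.3,0.08,1,0.96,1,3
rtcs,A'36,A',linear,2.1,506,474,506,6.6,1146,997,1215,965,21.8,0.13,1,0.61,1,3
rtcs,A'36,A',variance,2.1,506,465,510,6.5,1146,997,1241,,21.3,0.15,1,0.99,1,3
rtcs,A2,A,linear,3.1,323,16,347,11.4,744,388,828,485,28,0.13,1,0.01,0,2
rtcs,A2,A,variance,3.1,347,68,347,11.8,744,347,796,,27.6,0.12,1,0.17,0,2
rtcs,A'37,A',linear,1.3,313,298,313,6.1,707,549,828,692,14.7,0.1,1,0.95,1,3
rtcs,A'37,A',variance,1.3,313,288,313,3.8,455,417,707,,12.3,0.08,1,0.94,1,3
rtcs,A'38,A',linear,1.4,272,267,322,4.3,505,426,505,563,16.1,0.05,1,0,0,2
rtcs,A'38,A',variance,1.5,295,285,318,4.3,428,402,697,,15.5,0.05,1,0.88,1,3
rtcs,A'39,A',linear,,,,,8.8,980,548,1118,634,26.9,0.35,1,0.2,0,1
rtcs,A'39,A',variance,,,,,8.6,980,548,1118,,26.4,0.39,1,0.91,1,2
rtcs,B15,B,linear,,,,,5.8,520,328,819,210,15.2,0.05,0,1,1,2
rtcs,B15,B,variance,,,,,5.6,596,101,654,,15.6,0.36,1,0.9,1,2
rum-1,A5,A,linear,2.5,787,771,820,8.8,2360,2090,2360,2032,51.7,0.38,1,1,1,3
rum-1,A5,A,variance,2.6,842,787,858,9.2,2360,2185,2360,,50.8,0.41,1,1,1,3
rum-1,A7,A,linear,1.8,456,415,491,7,1123,610,1123,1241,19.4,0.1,1,0,0,2
rum-1,A7,A,variance,1.8,456,393,463,4.1,629,595,1050,,12.3,0.03,1,0.97,1,3
rum-1,A'41,A',linear,4.6,452,392,469,9.8,1246,787,1352,1023,33.2,0.06,1,0.74,1,3
rum-1,A'41,A',variance,4.5,452,401,482,9.6,1352,1107,1433,,34.3,0.12,1,0.99,1,3
rum-1,A4,A,linear,2.1,399,379,445,6.1,1068,941,1187,869,18.6,0.1,1,0.95,1,3
rum-1,A4,A,variance,2.4,542,507,542,7,1187,1103,1187,,19.8,0.31,1,0.99,1,3
rum-1,A'40,A',linear,4.4,385,343,385,12,689,647,1136,885,30,0.05,0,0.97,1,3
rum-1,A'40,A',variance,4.4,385,310,385,11.8,689,639,770,,29.7,0.17,1,0.97,1,3
rum-1,A6,A,linear,2.1,371,347,451,4.7,958,846,958,1700,29.4,0.25,1,1,1,3
rum-1,A6,A,variance,2.1,371,347,547,4.7,958,909,958,,28.9,0.28,1,0.94,1,3
rum-1,A'42,A',linear,3.2,295,178,352,5.5,627,499,627,585,20.7,0.14,1,0.93,1,3
rum-1,A'42,A',variance,2.8,225,140,297,5.2,627,548,627,,20.5,0.07,1,0.29,0,2
rum-1,C22,C,linear,,,,,5.4,1510,1289,1510,1270,15.2,0.85,1,1,1,2
rum-1,C22,C,variance,,,,,5.4,1867,1752,1897,,17.5,0.33,1,1,1,2
rum-1,C24,C,linear,,,,,4,540,482,637,656,11.6,0.5,1,0.94,1,2
rum-1,C24,C,variance,,,,,4,540,482,637,,11.5,0.46,1,0.91,1,2
rum-1,C23,C,linear,,,,,7.8,732,456,909,421,10.3,0.15,1,0,0,1
rum-1,C23,C,variance,,,,,,,,,,9.1,1,1,0.99,1,1
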