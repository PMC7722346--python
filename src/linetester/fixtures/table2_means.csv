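environment,condition,replicate,block,genotype,line,tester,role,yield,da,asi,pasp,easp,epp,sgc,base_index
DT,drought,1,1,TZEEI 102xTZEEI 95,TZEEI 102,TZEEI 95,hybrid,2707,50.8,2.5,2.0,2.5,0.9,3.0,15.66
OPT,rainfed,1,1,TZEEI 102xTZEEI 95,TZEEI 102,TZEEI 95,hybrid,3774,48.4,0.3,2.5,3.0,0.97,,
DT,drought,1,1,TZEEI 97xTZEEI 79,TZEEI 97,TZEEI 79,hybrid,2471,49.7,2.0,2.4,2.5,0.9,3.5,12.53
OPT,rainfed,1,1,TZEEI 97xTZEEI 79,TZEEI 97,TZEEI 79,hybrid,4292,48.4,1.1,2.9,2.7,0.93,,
DT,drought,1,1,TZEEI 71xTZEEI 79,TZEEI 71,TZEEI 79,hybrid,2253,51.3,2.5,2.3,2.9,0.8,3.8,8.26
OPT,rainfed,1,1,TZEEI 71xTZEEI 79,TZEEI 71,TZEEI 79,hybrid,4241,49.0,0.4,2.3,2.9,0.93,,
DT,drought,1,1,TZEEI 80xTZEEI 95,TZEEI 80,TZEEI 95,hybrid,1992,51.3,2.7,2.5,2.8,0.9,3.7,8.17
OPT,rainfed,1,1,TZEEI 80xTZEEI 95,TZEEI 80,TZEEI 95,hybrid,3755,49.8,-0.1,2.7,3.1,0.95,,
DT,drought,1,1,TZEEI 76xTZEEI 79,TZEEI 76,TZEEI 79,hybrid,1960,51.2,2.3,2.4,3.0,0.9,3.5,8.11
OPT,rainfed,1,1,TZEEI 76xTZEEI 79,TZEEI 76,TZEEI 79,hybrid,4368,49.0,0.4,1.9,2.5,0.96,,
DT,drought,1,1,TZEEI 74xTZEEI 79,TZEEI 74,TZEEI 79,hybrid,2055,49.7,2.7,2.5,2.7,0.8,3.5,8.08
OPT,rainfed,1,1,TZEEI 74xTZEEI 79,TZEEI 74,TZEEI 79,hybrid,3733,48.5,0.2,2.5,2.9,0.92,,
DT,drought,1,1,TZEEI 61xTZEEI 95,TZEEI 61,TZEEI 95,hybrid,2434,52.8,4.5,2.5,2.5,0.8,4.0,7.75
OPT,rainfed,1,1,TZEEI 61xTZEEI 95,TZEEI 61,TZEEI 95,hybrid,4150,48.3,0.5,2.9,2.9,0.99,,
DT,drought,1,1,TZEEI 82xTZEEI 79,TZEEI 82,TZEEI 79,hybrid,2060,50.5,2.2,2.4,2.6,0.7,3.7,7.75
OPT,rainfed,1,1,TZEEI 82xTZEEI 79,TZEEI 82,TZEEI 79,hybrid,4479,49.4,0.3,2.2,2.6,1.0,,
DT,drought,1,1,TZEEI 86xTZEEI 79,TZEEI 86,TZEEI 79,hybrid,2020,51.0,3.7,2.6,2.4,0.8,3.7,7.5
OPT,rainfed,1,1,TZEEI 86xTZEEI 79,TZEEI 86,TZEEI 79,hybrid,4538,48.8,0.6,2.2,2.5,0.98,,
DT,drought,1,1,TZEEI 100xTZEEI 63,TZEEI 100,TZEEI 63,hybrid,1913,52.2,2.3,2.3,2.7,0.8,3.8,7.41
OPT,rainfed,1,1,TZEEI 100xTZEEI 63,TZEEI 100,TZEEI 63,hybrid,4937,50.7,-0.0,2.3,2.5,0.98,,
DT,drought,1,1,TZEEI 67xTZEEI 79,TZEEI 67,TZEEI 79,hybrid,1906,52.5,2.2,2.4,2.5,0.8,4.2,6.82
OPT,rainfed,1,1,TZEEI 67xTZEEI 79,TZEEI 67,TZEEI 79,hybrid,4441,50.9,-0.2,1.9,2.4,0.92,,
DT,drought,1,1,TZEEI 98xTZEEI 63,TZEEI 98,TZEEI 63,hybrid,1982,51.8,2.7,2.8,2.6,0.9,3.8,6.6
OPT,rainfed,1,1,TZEEI 98xTZEEI 63,TZEEI 98,TZEEI 63,hybrid,4888,48.6,0.6,2.1,2.7,0.98,,
DT,drought,1,1,TZEEI 94xTZEEI 95,TZEEI 94,TZEEI 95,hybrid,1908,52.3,2.7,2.8,2.5,0.8,3.8,6.42
OPT,rainfed,1,1,TZEEI 94xTZEEI 95,TZEEI 94,TZEEI 95,hybrid,3453,47.9,0.4,2.7,3.1,0.98,,
DT,drought,1,1,TZEEI 83xTZEEI 79,TZEEI 83,TZEEI 79,hybrid,1961,50.2,2.8,2.4,2.7,0.8,4.0,6.08
OPT,rainfed,1,1,TZEEI 83xTZEEI 79,TZEEI 83,TZEEI 79,hybrid,4709,49.3,0.1,2.1,2.6,1.0,,
DT,drought,1,1,TZEEI 73xTZEEI 79,TZEEI 73,TZEEI 79,hybrid,1878,50.7,2.8,2.3,2.8,0.9,4.2,5.95
OPT,rainfed,1,1,TZEEI 73xTZEEI 79,TZEEI 73,TZEEI 79,hybrid,4491,49.1,1.5,2.1,2.9,0.99,,
DT,drought,1,1,TZEEI 64xTZEEI 79,TZEEI 64,TZEEI 79,hybrid,1994,50.7,2.5,2.6,2.8,0.8,4.2,5.8
OPT,rainfed,1,1,TZEEI 64xTZEEI 79,TZEEI 64,TZEEI 79,hybrid,4690,48.5,0.2,2.8,2.6,1.01,,
DT,drought,1,1,TZEEI 108xTZEEI 79,TZEEI 108,TZEEI 79,hybrid,1917,51.0,3.5,2.4,2.5,0.8,4.3,5.72
OPT,rainfed,1,1,TZEEI 108xTZEEI 79,TZEEI 108,TZEEI 79,hybrid,4435,50.3,1.0,2.1,2.8,1.01,,
DT,drought,1,1,TZEEI 71xTZEEI 95,TZEEI 71,TZEEI 95,hybrid,1981,50.7,3.0,2.8,2.8,0.8,3.5,5.64
OPT,rainfed,1,1,TZEEI 71xTZEEI 95,TZEEI 71,TZEEI 95,hybrid,4388,48.7,0.4,2.2,2.5,0.98,,
DT,drought,1,1,TZEEI 80xTZEEI 79,TZEEI 80,TZEEI 79,hybrid,1886,51.7,3.2,2.6,2.8,0.8,3.7,5.56
OPT,rainfed,1,1,TZEEI 80xTZEEI 79,TZEEI 80,TZEEI 79,hybrid,4682,49.1,0.6,2.2,2.9,1.04,,
DT,drought,1,1,TZEEI 76xTZEEI 95,TZEEI 76,TZEEI 95,hybrid,1853,51.8,2.7,2.8,2.8,0.7,3.3,5.29
OPT,rainfed,1,1,TZEEI 76xTZEEI 95,TZEEI 76,TZEEI 95,hybrid,3987,48.3,0.1,2.1,3.0,0.99,,
DT,drought,1,1,TZEEI 59xTZEEI 79,TZEEI 59,TZEEI 79,hybrid,1922,51.5,3.5,2.6,2.7,0.8,4.0,5.26
OPT,rainfed,1,1,TZEEI 59xTZEEI 79,TZEEI 59,TZEEI 79,hybrid,3513,49.6,1.0,2.3,2.9,0.9,,
DT,drought,1,1,TZEEI 72xTZEEI 79,TZEEI 72,TZEEI 79,hybrid,1948,51.2,3.0,2.6,2.8,0.8,4.2,5.19
OPT,rainfed,1,1,TZEEI 72xTZEEI 79,TZEEI 72,TZEEI 79,hybrid,4669,48.9,0.2,2.2,2.5,0.99,,
DT,drought,1,1,TZEEI 9xTZEEI 79,TZEEI 9,TZEEI 79,hybrid,1928,49.2,3.0,2.5,2.6,0.8,4.3,5.05
OPT,rainfed,1,1,TZEEI 9xTZEEI 79,TZEEI 9,TZEEI 79,hybrid,3382,48.9,0.3,2.4,3.1,0.89,,
DT,drought,1,1,TZEEI 98xTZEEI 95,TZEEI 98,TZEEI 95,hybrid,1665,52.5,2.3,2.8,2.8,0.8,3.7,4.79
OPT,rainfed,1,1,TZEEI 98xTZEEI 95,TZEEI 98,TZEEI 95,hybrid,3626,50.0,0.1,2.5,2.7,0.96,,
DT,drought,1,1,TZEEI 100xTZEEI 79,TZEEI 100,TZEEI 79,hybrid,1837,53.0,2.0,2.6,2.9,0.8,4.0,4.64
OPT,rainfed,1,1,TZEEI 100xTZEEI 79,TZEEI 100,TZEEI 79,hybrid,4084,51.3,1.3,2.7,2.9,1.03,,
DT,drought,1,1,TZEEI 81xTZEEI 79,TZEEI 81,TZEEI 79,hybrid,2060,52.2,4.2,3.0,2.8,0.7,4.3,1.72
OPT,rainfed,1,1,TZEEI 81xTZEEI 79,TZEEI 81,TZEEI 79,hybrid,5382,49.8,0.2,1.8,2.3,0.99,,
DT,drought,1,1,2008 SYN EE-Y DT STR,,,check,1525,51.8,3.2,2.6,3.0,0.7,4.2,0.96
OPT,rainfed,1,1,2008 SYN EE-Y DT STR,,,check,3652,50.7,0.7,2.5,3.1,0.89,,
DT,drought,1,1,TZEEI 61xTZEEI 63,TZEEI 61,TZEEI 63,hybrid,1111,53.2,7.0,3.3,3.3,0.7,5.0,-10.19
OPT,rainfed,1,1,TZEEI 61xTZEEI 63,TZEEI 61,TZEEI 63,hybrid,2551,52.2,1.3,3.0,3.2,0.91,,
DT,drought,1,1,TZEEI 58xTZEEI 63,TZEEI 58,TZEEI 63,hybrid,753,53.2,6.3,3.2,3.7,0.6,4.0,-10.38
OPT,rainfed,1,1,TZEEI 58xTZEEI 63,TZEEI 58,TZEEI 63,hybrid,2743,50.8,0.7,2.7,3.3,0.95,,
DT,drought,1,1,TZEEI 115xTZEEI 63,TZEEI 115,TZEEI 63,hybrid,728,53.5,4.8,3.5,3.6,0.5,4.5,-11.83
OPT,rainfed,1,1,TZEEI 115xTZEEI 63,TZEEI 115,TZEEI 63,hybrid,2148,51.2,1.1,3.2,3.5,0.88,,
DT,drought,1,1,TZEEI 75xTZEEI 63,TZEEI 75,TZEEI 63,hybrid,901,55.8,5.5,3.8,3.7,0.5,4.3,-12.92
OPT,rainfed,1,1,TZEEI 75xTZEEI 63,TZEEI 75,TZEEI 63,hybrid,1834,50.8,2.5,3.2,3.8,0.9,,
DT,drought,1,1,TZEEI 76xTZEEI 63,TZEEI 76,TZEEI 63,hybrid,761,53.2,7.0,3.7,3.7,0.5,4.8,-14.99
OPT,rainfed,1,1,TZEEI 76xTZEEI 63,TZEEI 76,TZEEI 63,hybrid,2527,50.5,1.5,3.3,3.1,0.95,,
DT,drought,1,1,TZEEI 102xTZEEI 63,TZEEI 102,TZEEI 63,hybrid,462,55.2,5.5,3.8,3.8,0.5,4.3,-15.09
OPT,rainfed,1,1,TZEEI 102xTZEEI 63,TZEEI 102,TZEEI 63,hybrid,1203,51.7,1.9,3.2,4.1,0.71,,
DT,drought,1,1,TZEEI 74xTZEEI 63,TZEEI 74,TZEEI 63,hybrid,728,52.2,6.3,3.8,3.8,0.6,5.5,-17.1
OPT,rainfed,1,1,TZEEI 74xTZEEI 63,TZEEI 74,TZEEI 63,hybrid,2178,50.0,0.8,3.0,3.5,0.89,,
DT,drought,1,1,TZEEI 62xTZEEI 63,TZEEI 62,TZEEI 63,hybrid,503,54.3,8.8,3.8,4.1,0.5,5.3,-21.25
OPT,rainfed,1,1,TZEEI 62xTZEEI 63,TZEEI 62,TZEEI 63,hybrid,1632,51.9,1.9,2.8,3.8,0.75,,
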