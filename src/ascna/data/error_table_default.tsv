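# confidence=0.9 beta_grid=0.2,0.5,0.8,1.0 reps=1000 seed=2024
nsnps	cov	error
5	10	0.2921000000000001
5	20	0.21499999999999997
5	50	0.14100000000000001
5	100	0.0991
5	200	0.07099999999999995
5	500	0.041000000000000036
10	10	0.25820000000000004
10	20	0.19999999999999996
10	50	0.119
10	100	0.07899999999999996
10	200	0.05400000000000005
10	500	0.03500000000000003
20	10	0.21899999999999997
20	20	0.14610000000000004
20	50	0.09399999999999997
20	100	0.06799999999999995
20	200	0.04600000000000004
20	500	0.030000000000000027
50	10	0.16100000000000003
50	20	0.123
50	50	0.07499999999999996
50	100	0.052000000000000046
50	200	0.038000000000000034
50	500	0.02300000000000002
100	10	0.137
100	20	0.09799999999999998
100	50	0.06299999999999994
100	100	0.04300000000000004
100	200	0.030000000000000027
100	500	0.019000000000000017
200	10	0.11499999999999999
200	20	0.08099999999999996
200	50	0.049000000000000044
200	100	0.03600000000000003
200	200	0.027000000000000024
200	500	0.017000000000000015
400	10	0.10099999999999998
400	20	0.06699999999999995
400	50	0.04400000000000004
400	100	0.030000000000000027
400	200	0.02200000000000002
400	500	0.013000000000000012
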