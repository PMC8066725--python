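run_id,flow_coded,pctB_start_coded,pctB_end_coded,flow_natural,pctB_start_natural,pctB_end_natural,Rs_3_4,Rs_4_5,Rs_5_6,Rs_6_7,run_time
1,0,0,0,0.5,5,75,1.50,3.62,3.34,1.74,2.761
2,1,0,1,0.6,5,100,1.22,3.68,2.72,1.31,2.326
3,0,0,0,0.5,5,75,1.77,4.53,4.10,2.02,2.775
4,0,-1,1,0.5,0,100,1.08,2.46,2.12,1.22,2.658
5,-1,0,-1,0.4,5,50,2.01,3.93,3.68,2.20,3.574
6,-1,0,1,0.4,5,100,1.00,2.83,2.79,1.27,2.659
7,0,1,1,0.5,10,100,1.18,3.53,3.08,1.47,2.210
8,0,0,0,0.5,5,75,1.36,3.62,2.89,1.41,2.759
9,0,1,-1,0.5,10,50,2.35,5.40,4.81,2.83,2.924
10,1,-1,0,0.6,0,75,1.25,3.60,3.49,1.75,2.892
11,0,-1,-1,0.5,0,50,1.80,3.88,4.01,2.35,3.699
12,-1,-1,0,0.4,0,75,1.13,3.38,3.05,1.61,3.242
13,-1,1,0,0.4,10,75,1.49,3.76,3.01,1.58,2.705
14,1,1,0,0.6,10,75,1.82,4.30,3.63,1.88,2.298
15,1,0,-1,0.6,5,50,2.02,4.33,4.91,2.92,3.199
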