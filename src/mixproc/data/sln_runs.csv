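run_id,p80_pct,us_time_min,cw,gb,gds,ps_nm,pdi,zp_abs_mv
1,0.0,1.0,0.0,0.0,1.0,341.8,0.82,39.47
2,0.0,1.0,0.0,1.0,0.0,389.6,0.214,45.53
3,0.0,1.0,1.0,0.0,0.0,303.1,0.278,47.5
4,0.0,1.0,0.0,0.5,0.5,382.6,0.408,45.43
5,0.0,1.0,0.5,0.0,0.5,354.9,0.31,43.33
6,0.0,1.0,0.5,0.5,0.0,370.3,0.27,37.83
7,0.0,1.0,0.3333333333333333,0.3333333333333333,0.3333333333333333,399.9,0.408,40.5
8,50.0,1.0,0.0,0.0,1.0,145.8,0.428,33.33
9,50.0,1.0,0.0,1.0,0.0,193.1,0.32,28.73
10,50.0,1.0,1.0,0.0,0.0,182.9,0.283,34.87
11,50.0,1.0,0.0,0.5,0.5,186.9,0.466,34.23
12,50.0,1.0,0.5,0.0,0.5,208.0,0.308,31.0
13,50.0,1.0,0.5,0.5,0.0,197.7,0.248,34.9
14,50.0,1.0,0.3333333333333333,0.3333333333333333,0.3333333333333333,241.3,0.31,33.1
15,100.0,1.0,0.0,0.0,1.0,244.5,0.488,11.23
16,100.0,1.0,0.0,1.0,0.0,272.2,0.121,8.1
17,100.0,1.0,1.0,0.0,0.0,83.16,0.543,10.87
18,100.0,1.0,0.0,0.5,0.5,469.9,0.637,12.47
19,100.0,1.0,0.5,0.0,0.5,284.8,0.22,15.1
20,100.0,1.0,0.5,0.5,0.0,21.88,0.43,3.06
21,100.0,1.0,0.3333333333333333,0.3333333333333333,0.3333333333333333,24.33,0.537,5.58
22,0.0,5.0,0.0,0.0,1.0,215.5,0.388,41.07
23,0.0,5.0,0.0,1.0,0.0,245.2,0.279,45.3
24,0.0,5.0,1.0,0.0,0.0,243.5,0.27,45.07
25,0.0,5.0,0.0,0.5,0.5,234.8,0.3,41.43
26,0.0,5.0,0.5,0.0,0.5,242.5,0.29,44.9
27,0.0,5.0,0.5,0.5,0.0,245.1,0.23,41.13
28,0.0,5.0,0.3333333333333333,0.3333333333333333,0.3333333333333333,261.1,0.248,43.9
29,50.0,5.0,0.0,0.0,1.0,117.4,0.346,31.43
30,50.0,5.0,0.0,1.0,0.0,122.8,0.45,34.3
31,50.0,5.0,1.0,0.0,0.0,106.6,0.299,34.8
32,50.0,5.0,0.0,0.5,0.5,131.6,0.433,31.23
33,50.0,5.0,0.5,0.0,0.5,127.7,0.415,29.67
34,50.0,5.0,0.5,0.5,0.0,150.2,0.244,33.3
35,50.0,5.0,0.3333333333333333,0.3333333333333333,0.3333333333333333,159.1,0.26,33.47
36,100.0,5.0,0.0,0.0,1.0,203.1,0.4,11.37
37,100.0,5.0,0.0,1.0,0.0,452.6,0.295,8.6
38,100.0,5.0,1.0,0.0,0.0,252.1,0.22,17.6
39,100.0,5.0,0.0,0.5,0.5,350.3,0.3,9.4
40,100.0,5.0,0.5,0.0,0.5,344.8,0.202,14.93
41,100.0,5.0,0.5,0.5,0.0,25.86,0.646,3.8
42,100.0,5.0,0.3333333333333333,0.3333333333333333,0.3333333333333333,29.86,0.604,3.17
43,0.0,10.0,0.0,0.0,1.0,225.0,0.627,39.63
44,0.0,10.0,0.0,1.0,0.0,229.3,0.283,40.03
45,0.0,10.0,1.0,0.0,0.0,246.1,0.245,42.43
46,0.0,10.0,0.0,0.5,0.5,225.2,0.36,38.97
47,0.0,10.0,0.5,0.0,0.5,249.4,0.368,40.53
48,0.0,10.0,0.5,0.5,0.0,248.7,0.262,41.73
49,0.0,10.0,0.3333333333333333,0.3333333333333333,0.3333333333333333,253.9,0.451,38.1
50,50.0,10.0,0.0,0.0,1.0,108.7,0.462,32.0
51,50.0,10.0,0.0,1.0,0.0,113.9,0.494,35.87
51r,50.0,10.0,0.0,1.0,0.0,111.2,0.41,21.67
52,50.0,10.0,1.0,0.0,0.0,98.83,0.384,36.43
52r,50.0,10.0,1.0,0.0,0.0,131.2,0.275,32.83
53,50.0,10.0,0.0,0.5,0.5,127.5,0.468,33.53
54,50.0,10.0,0.5,0.0,0.5,125.1,0.399,30.07
55,50.0,10.0,0.5,0.5,0.0,142.3,0.262,33.73
55r,50.0,10.0,0.5,0.5,0.0,128.3,0.307,33.1
56,50.0,10.0,0.3333333333333333,0.3333333333333333,0.3333333333333333,160.5,0.296,34.2
57,100.0,10.0,0.0,0.0,1.0,287.2,0.89,10.19
58,100.0,10.0,0.0,1.0,0.0,712.8,0.292,7.56
59,100.0,10.0,1.0,0.0,0.0,208.7,0.37,15.67
60,100.0,10.0,0.0,0.5,0.5,447.0,0.439,12.7
61,100.0,10.0,0.5,0.0,0.5,316.8,0.251,14.13
62,100.0,10.0,0.5,0.5,0.0,19.44,0.376,4.03
63,100.0,10.0,0.3333333333333333,0.3333333333333333,0.3333333333333333,26.07,0.472,3.41
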