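fish_id,capture_location,movement_group,standard_length_cm,weight_g,release_date,dp_days,dr,ri_nr,ri_ar,ri_sw,ri_cv,eoph
1,AR,AR,26.0,590,2011-07-30,91,98.90,0.00,100.00,0.00,0.00,0
2,AR,T,31.2,1005,2011-07-30,155,12.26,96.34,3.66,0.00,0.00,1
3,AR,NPH,33.5,1220,2011-07-30,106,86.79,51.64,48.36,0.00,0.00,3
4,AR,NPH,34.3,1125,2011-07-29,209,96.17,54.50,45.48,0.02,0.00,41
5,AR,T,32.4,1050,2011-07-29,72,4.17,26.67,60.00,0.00,13.33,1
6,AR,AR,24.7,480,2011-07-29,150,98.67,28.91,71.03,0.00,0.06,2
7,NR,NR,21.6,330,2011-06-22,22,95.45,100.00,0.00,0.00,0.00,0
8,NR,NR,31.6,985,2011-06-22,138,78.26,99.58,0.27,0.00,0.15,6
9,AR,NR,31.3,915,2011-06-22,27,96.30,98.97,1.03,0.00,0.00,1
10,AR,NPH,28.2,650,2011-07-29,68,100.00,44.23,55.77,0.00,0.00,1
11,AR,NR,23.6,385,2011-06-21,26,92.31,99.85,0.15,0.00,0.00,1
12,AR,AR,34.6,1140,2011-06-21,114,98.25,0.00,100.00,0.00,0.00,0
13,NR,NR,28.8,795,2011-06-21,52,100.00,100.00,0.00,0.00,0.00,0
14,NR,NR,29.1,750,2011-06-22,196,77.65,99.90,0.10,0.00,0.00,1
15,NR,NR,33.0,1045,2011-06-22,148,97.97,99.88,0.12,0.00,0.00,2
16,AR,T,19.3,225,2011-06-16,38,47.53,0.00,3.41,42.64,53.94,1
17,NR,NR,26.8,650,2011-06-17,201,94.53,99.88,0.12,0.00,0.00,2
18,NR,NR,23.6,420,2011-06-17,41,100.00,100.00,0.00,0.00,0.00,0
19,NR,NR,27.2,635,2011-06-17,193,72.69,100.00,0.00,0.00,0.00,0
20,AR,AR,23.2,395,2011-06-21,248,96.37,0.00,100.00,0.00,0.00,0
21,AR,AR,30.9,835,2011-06-18,207,90.34,21.54,78.46,0.00,0.00,1
22,AR,NPH,26.9,650,2011-06-16,60,96.67,61.75,38.25,0.00,0.00,1
23,AR,AR,27.2,535,2011-06-21,154,91.56,1.09,98.91,0.00,0.00,2
24,NR,NR,27.8,870,2011-06-17,201,88.06,99.93,0.07,0.00,0.00,2
25,AR,NR,23.4,410,2011-06-17,22,80.00,100.00,0.00,0.00,0.00,0
26,AR,NPH,27.9,740,2011-06-19,134,95.52,63.45,36.50,0.00,0.05,11
27,AR,AR,26.6,655,2011-06-16,252,75.16,24.11,75.84,0.04,0.00,2
28,AR,AR,24.5,475,2011-06-16,158,96.20,12.42,87.47,0.08,0.03,2
29,AR,AR,23.7,405,2011-06-16,260,71.92,0.00,99.66,0.00,0.34,1
30,AR,T,31.5,995,2011-06-16,193,20.73,85.98,13.86,0.00,0.16,2
31,AR,AR,24.7,525,2011-06-16,146,98.63,18.02,81.91,0.07,0.00,3
32,NR,NR,26.0,550,2011-05-30,219,94.06,100.00,0.00,0.00,0.00,0
33,AR,AR,25.3,485,2011-05-30,164,99.39,0.16,99.84,0.00,0.00,1
34,AR,NPH,18.3,205,2011-05-30,269,73.98,47.84,52.16,0.00,0.00,7
35,NR,NR,30.0,785,2011-05-30,220,95.91,99.98,0.02,0.00,0.00,1
36,NR,NR,32.4,955,2011-05-30,186,75.27,99.82,0.18,0.00,0.00,3
37,AR,T,18.5,200,2011-07-28,83,9.64,56.00,40.00,2.00,2.00,2
38,AR,AR,18.2,190,2011-07-28,102,95.10,0.00,100.00,0.00,0.00,0
39,NR,AR,32.6,1140,2011-07-29,111,93.69,2.86,97.09,0.00,0.05,1
40,NR,NR,31.4,935,2011-07-29,161,95.03,99.79,0.21,0.00,0.00,3
41,NR,NR,26.6,545,2011-07-29,117,95.73,99.11,0.89,0.00,0.00,4
42,NR,NR,20.5,335,2011-07-29,79,100.00,100.00,0.00,0.00,0.00,0
43,NR,NR,25.6,505,2011-07-29,159,73.58,99.71,0.29,0.00,0.00,1
44,NR,NR,32.2,970,2011-07-29,160,93.75,99.88,0.12,0.00,0.00,2
45,AR,AR,21.4,315,2011-07-29,35,80.00,0.00,100.00,0.00,0.00,0
46,NR,NR,35.0,1215,2011-09-16,125,76.80,98.19,1.81,0.00,0.00,9
47,NR,T,27.4,690,2011-09-16,166,28.92,99.73,0.00,0.00,0.27,1
48,NR,NR,20.0,225,2011-09-16,110,72.73,99.91,0.09,0.00,0.00,1
49,NR,NR,25.9,580,2011-09-16,109,71.81,99.94,0.06,0.00,0.00,1
50,NR,T,21.5,335,2011-09-16,77,45.45,99.64,0.00,0.00,0.36,1
51,AR,AR,25.0,525,2011-10-24,63,88.89,0.00,100.00,0.00,0.00,0
52,NR,NR,22.2,340,2011-09-16,32,93.75,99.76,0.00,0.00,0.24,1
53,NR,NR,19.6,220,2011-09-16,110,70.27,100.00,0.00,0.00,0.00,0
54,NR,NR,19.4,245,2011-09-16,54,75.56,98.48,0.38,0.00,1.14,2
55,NR,T,22.9,375,2011-09-16,26,34.62,100.00,0.00,0.00,0.00,0
56,NR,T,24.8,480,2011-09-16,110,38.18,100.00,0.00,0.00,0.00,0
57,NR,NR,23.6,420,2011-09-16,109,74.31,100.00,0.00,0.00,0.00,0
58,NR,T,24.9,290,2011-09-16,106,25.47,96.35,0.66,0.00,2.99,2
59,NR,T,17.0,155,2011-09-16,110,23.64,100.00,0.00,0.00,0.00,0
60,NR,T,22.9,395,2011-09-17,30,16.67,100.00,0.00,0.00,0.00,0
61,NR,NR,18.3,210,2011-09-17,110,95.45,99.95,0.05,0.00,0.00,1
62,AR,AR,18.2,230,2011-10-31,79,78.48,0.00,100.00,0.00,0.00,0
63,SW,T,30.3,945,2011-10-20,43,37.21,98.70,0.00,0.00,1.30,1
64,AR,NR,26.2,605,2011-09-30,29,89.66,94.04,5.96,0.00,0.00,1
65,AR,T,19.9,310,2011-11-03,29,6.90,0.00,60.00,0.00,40.00,1
66,NR,NR,32.0,975,2011-09-07,54,87.04,100.00,0.00,0.00,0.00,0
67,SW,NR,19.7,245,2011-10-09,102,74.71,99.64,0.36,0.00,0.00,1
68,NR,NR,27.9,750,2011-09-07,60,85.00,99.76,0.24,0.00,0.00,1
69,AR,AR,31.6,1010,2011-09-11,59,88.14,0.00,100.00,0.00,0.00,0
70,AR,AR,21.6,285,2011-09-11,57,94.74,0.00,100.00,0.00,0.00,0
71,AR,AR,20.1,270,2011-09-11,30,96.67,0.00,100.00,0.00,0.00,0
72,AR,T,24.0,415,2011-09-11,57,40.35,95.61,4.39,0.00,0.00,1
73,NR,NR,25.5,550,2011-09-07,26,92.31,100.00,0.00,0.00,0.00,0
74,AR,AR,31.6,885,2011-07-30,161,95.65,17.72,82.24,0.03,0.00,2
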