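compound_id,log_kw_ODS,s_ODS,log_kw_IAM,s_IAM,log_kw_Cholester,s_Cholester
1,0.97,2.70,0.55,2.10,0.20,1.25
2,1.30,3.12,1.00,2.88,0.57,1.84
3,1.22,3.02,0.80,2.51,0.46,1.70
4,1.33,3.15,0.84,2.60,0.62,1.82
5,1.78,3.56,1.24,3.25,1.18,2.61
6,2.53,4.49,1.85,4.11,2.05,3.61
7,1.28,3.09,0.81,2.38,0.58,1.92
8,1.90,3.82,1.33,3.33,1.29,2.75
9,1.30,3.02,0.81,2.45,0.57,1.82
10,1.95,3.91,1.42,3.39,1.36,2.81
11,2.36,4.44,1.82,4.39,1.82,3.55
12,1.75,3.61,1.21,3.11,1.11,2.55
13,2.37,4.36,1.70,3.85,1.92,3.58
14,1.37,3.15,0.91,2.58,0.65,1.92
15,2.85,4.90,2.05,4.45,2.41,4.15
16,2.80,4.88,2.11,4.51,2.37,4.19
17,3.16,5.33,2.42,5.01,2.77,4.61
18,2.12,4.06,1.29,3.23,1.43,3.12
19,1.74,3.48,0.96,2.72,1.20,2.78
20,2.43,4.39,1.69,3.90,2.03,3.68
21,2.26,4.20,1.42,3.51,1.66,3.33
22,1.67,3.48,1.11,3.02,1.22,2.68
23,1.91,3.82,1.19,3.13,1.53,3.05
24,2.25,4.22,1.27,3.25,1.34,2.95
25,2.75,4.85,2.08,4.55,2.36,4.05
26,2.65,4.59,2.02,4.44,2.29,4.15
27,3.46,5.68,3.23,6.30,2.92,4.85
28,2.53,4.45,1.70,3.90,2.05,3.66
29,2.49,4.51,1.91,4.22,2.34,4.02
30,2.12,4.01,1.53,3.52,1.88,3.50
31,2.93,5.02,2.26,4.68,2.77,4.42
32,2.93,5.06,2.22,4.81,2.86,4.65
33,1.98,3.99,1.47,3.62,1.69,2.94
34,2.59,4.62,1.71,3.91,2.27,3.80
35,3.09,5.33,2.14,4.48,2.80,4.61
36,2.74,4.85,1.85,4.05,2.34,3.60
37,2.43,4.60,1.73,3.84,1.96,3.65
38,3.29,5.70,2.64,5.41,3.20,5.20
39,3.41,5.20,2.57,5.32,3.19,5.30
40,3.48,5.90,3.26,6.40,3.86,6.02
41,2.90,5.02,3.26,6.45,2.23,3.75
42,3.28,5.10,2.34,4.78,2.83,4.71
43,3.59,5.85,2.48,5.18,2.90,4.80
44,3.60,5.62,2.39,4.81,3.01,4.70
45,3.35,5.55,2.15,4.69,2.74,4.59
46,3.04,5.30,2.51,5.22,3.15,5.05
47,3.09,5.24,2.59,5.14,3.09,5.06
48,3.12,5.11,2.65,5.21,3.24,4.90
49,3.31,5.41,2.78,5.50,3.40,5.33
50,3.22,5.55,2.81,5.62,3.39,5.34
51,3.28,5.61,2.11,4.51,2.68,4.55
52,3.14,5.36,2.43,5.02,3.07,5.02
53,2.93,5.02,2.51,5.17,3.21,5.15
54,3.35,5.55,2.73,5.61,3.31,5.22
55,3.32,5.66,2.72,5.44,3.36,5.35
56,3.01,4.95,2.02,4.31,2.34,4.05
57,3.11,5.05,2.52,5.06,2.98,4.85
58,3.55,5.65,3.22,6.32,3.74,5.62
59,3.61,5.85,3.15,6.01,3.67,5.75
60,4.02,6.45,3.17,6.18,3.68,5.82
61,2.80,4.92,2.07,4.45,2.33,4.02
62,3.23,5.44,2.41,5.01,2.84,4.70
63,2.46,4.44,1.81,4.08,1.94,3.66
64,3.56,5.81,2.68,5.44,3.22,5.12
65,4.29,6.66,3.40,6.55,4.12,6.20
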