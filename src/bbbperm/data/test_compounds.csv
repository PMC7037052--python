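compound_id,A,B,S,E,V,TPSA,alpha,MW,log_bb_lfer_ref,log_bb_qsar_ODS_ref,log_bb_qsar_IAM_ref,log_bb_qsar_Cholester_ref
1,0,1.34,1.73,1.88,1.8144,48.27,27.55,242.28,0.21,0.19,0.20,0.22
2,0,1.34,1.67,1.90,1.9553,48.27,29.30,256.30,0.32,0.21,0.22,0.24
3,0,1.33,1.81,2.01,1.9368,48.27,29.37,276.72,0.26,0.21,0.22,0.24
4,0,1.28,1.80,2.01,1.9368,48.27,29.37,276.72,0.30,0.21,0.22,0.24
5,0,1.33,1.84,2.03,1.9368,48.27,29.37,276.72,0.24,0.21,0.22,0.24
6,0,1.26,1.91,2.14,2.0592,48.27,31.20,311.17,0.34,0.24,0.24,0.26
7,0,1.67,2.13,1.94,2.0297,74.57,30.27,286.29,-0.16,-0.13,-0.11,-0.10
8,0,1.67,2.07,1.97,2.1706,74.57,32.02,300.31,-0.04,-0.11,-0.09,-0.08
9,0,1.88,2.26,2.01,2.2293,83.80,32.57,316.31,-0.28,-0.23,-0.21,-0.20
10,0,1.88,2.26,2.01,2.3702,83.80,34.40,330.34,-0.20,-0.21,-0.19,-0.17
11,0,1.65,2.24,2.09,2.1521,74.57,32.09,320.73,-0.12,-0.10,-0.09,-0.07
12,0,1.68,2.14,1.94,2.1706,74.57,32.09,300.31,-0.10,-0.11,-0.09,-0.07
13,0,1.68,2.08,1.96,2.3115,74.57,33.85,314.38,0.02,-0.09,-0.07,-0.05
14,0,1.88,2.24,1.98,2.3702,83.80,34.40,330.34,-0.20,-0.21,-0.20,-0.18
15,0,1.62,2.20,2.07,2.2930,74.57,33.92,334.76,0.00,-0.08,-0.07,-0.05
16,0,1.66,2.25,2.09,2.2930,74.57,33.92,334.76,-0.05,-0.08,-0.07,-0.05
17,0,1.59,2.32,2.20,2.4154,74.57,35.74,369.20,0.05,-0.06,-0.05,-0.03
18,0,1.46,2.07,2.24,1.9603,61.41,30.82,280.31,0.06,0.06,0.07,0.09
19,0,1.46,2.01,2.26,2.1012,61.41,32.57,294.34,0.17,0.07,0.08,0.10
20,0,1.46,2.01,2.26,2.1012,61.41,32.57,294.34,0.17,0.08,0.08,0.11
21,0,1.46,1.95,2.29,2.2421,61.41,34.33,308.37,0.29,0.09,0.10,0.12
22,0,1.66,2.17,2.28,2.1599,70.64,33.12,310.34,-0.04,-0.05,-0.03,-0.02
23,0,1.66,2.19,2.31,2.1599,70.64,33.12,310.34,-0.05,-0.05,-0.03,-0.01
24,0,1.45,2.15,2.36,2.0827,61.41,32.64,314.75,0.11,0.07,0.08,0.10
25,0,1.40,2.13,2.36,2.0827,61.41,32.64,314.75,0.16,0.08,0.09,0.11
26,0,1.45,2.18,2.39,2.0827,61.41,32.64,314.75,0.09,0.08,0.09,0.11
27,0,1.38,2.25,2.50,2.2051,61.41,34.47,349.20,0.19,0.10,0.11,0.13
28,0,1.38,2.22,2.48,2.2051,61.41,34.47,349.20,0.21,0.09,0.10,0.12
29,0,1.42,2.19,2.46,2.1404,48.27,33.92,290.32,0.15,0.26,0.27,0.29
30,0,1.43,2.13,2.48,2.2813,48.27,35.68,304.35,0.26,0.27,0.28,0.30
31,0,1.43,2.13,2.48,2.2813,48.27,35.68,304.35,0.26,0.28,0.29,0.31
32,0,1.43,2.13,2.48,2.2813,48.27,35.68,304.35,0.26,0.28,0.29,0.31
33,0,1.63,2.29,2.50,2.3400,57.50,36.23,320.35,0.05,0.15,0.17,0.19
34,0,1.63,2.32,2.52,2.3400,57.50,36.23,320.35,0.04,0.16,0.17,0.19
35,0,1.63,2.32,2.52,2.4809,57.50,38.05,334.41,0.11,0.18,0.19,0.21
36,0,1.43,2.07,2.50,2.4222,48.27,37.43,318.37,0.38,0.29,0.30,0.32
37,0,1.41,2.27,2.58,2.2628,48.27,35.75,324.76,0.20,0.27,0.28,0.30
38,0,1.37,2.25,2.58,2.2628,48.27,35.75,324.76,0.25,0.28,0.29,0.31
39,0,1.41,2.30,2.61,2.2628,48.27,35.75,324.76,0.19,0.28,0.29,0.31
40,0,1.34,2.37,2.71,2.3852,48.27,37.57,359.21,0.29,0.30,0.31,0.34
41,0,1.43,2.19,2.45,2.2813,48.27,35.75,304.35,0.22,0.28,0.30,0.31
42,0,1.42,2.27,2.60,2.4037,48.27,37.57,338.82,0.28,0.30,0.31,0.33
43,0,1.42,2.27,2.60,2.4037,48.27,37.57,338.82,0.28,0.30,0.31,0.33
44,0,1.42,2.27,2.60,2.4037,48.27,37.57,338.82,0.28,0.30,0.31,0.33
45,0,1.43,2.14,2.48,2.4222,48.27,37.50,318.41,0.33,0.30,0.30,0.33
46,0,1.43,2.08,2.50,2.5631,48.27,39.26,332.44,0.45,0.31,0.32,0.35
47,0,1.43,2.08,2.50,2.5631,48.27,39.26,332.44,0.45,0.31,0.32,0.35
48,0,1.43,2.22,2.63,2.5446,48.27,39.26,352.85,0.38,0.31,0.32,0.35
49,0,1.43,2.22,2.63,2.5446,48.27,39.33,352.85,0.38,0.31,0.32,0.35
50,0,1.43,2.22,2.63,2.5446,48.27,39.33,352.85,0.38,0.31,0.32,0.35
51,0,1.63,2.32,2.52,2.6218,57.50,39.88,348.44,0.19,0.19,0.20,0.23
52,0,1.64,2.27,2.54,2.9036,57.50,41.63,362.47,0.37,0.21,0.22,0.25
53,0,1.63,2.41,2.67,2.7442,57.50,41.70,382.88,0.23,0.21,0.22,0.25
54,0,1.63,2.41,2.67,2.7442,57.50,41.70,382.88,0.23,0.21,0.22,0.25
55,0,1.63,2.41,2.61,2.7442,57.50,41.70,382.88,0.22,0.21,0.22,0.25
56,0,1.43,2.22,2.63,2.5446,48.27,39.33,352.85,0.38,0.31,0.32,0.34
57,0,1.41,2.30,2.60,2.4037,48.27,37.57,338.82,0.27,0.29,0.31,0.33
58,0,1.41,2.38,2.75,2.5261,48.27,39.40,373.27,0.31,0.31,0.33,0.35
59,0,1.41,2.38,2.75,2.5261,48.27,39.40,373.27,0.31,0.31,0.33,0.35
60,0,1.41,2.38,2.75,2.5261,48.27,39.40,373.27,0.31,0.32,0.33,0.35
61,0,1.43,2.20,2.45,2.4222,48.27,37.58,318.37,0.29,0.29,0.30,0.32
62,0,1.43,2.14,2.48,2.5631,48.27,39.33,332.40,0.41,0.31,0.32,0.34
63,0,1.42,2.28,2.58,2.5446,48.27,39.40,352.82,0.34,0.30,0.32,0.34
64,0,1.42,2.31,2.60,2.5446,48.27,39.40,352.82,0.33,0.31,0.32,0.35
65,0,1.35,2.38,2.71,2.6670,48.27,41.22,387.26,0.43,0.34,0.35,0.37
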