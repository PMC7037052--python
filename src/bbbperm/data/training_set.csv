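compound_id,cas,A,B,S,E,V,log_bb_exp
1,23830-88-8,0.45,0.90,1.22,1.560,1.5317,0.16
2,21571-08-4,0.45,0.86,1.30,1.690,1.6541,0.47
3,38941-33-2,0.45,0.86,1.54,2.240,1.8119,0.58
4,4205-93-0,0.39,0.90,1.36,1.920,1.6369,0.33
5,40065-09-6,0.45,0.86,1.38,1.870,1.7067,0.41
6,4205-90-7,0.55,1.16,1.34,1.600,1.5317,0.19
7,73590-58-6,0.35,2.05,3.18,2.670,2.5161,-0.82
8,28981-97-7,0,1.55,2.50,2.896,2.2041,-0.04
9,84379-13-5,0,1.55,2.84,2.520,2.7008,-0.09
10,78755-81-4,0,1.50,2.63,1.910,2.0884,-0.29
11,59467-70-8,0,1.38,2.01,2.570,2.2628,0.32
12,99632-94-7,0,1.48,2.52,1.920,2.2773,-0.25
13,2507-81-5,0.75,0.94,1.52,1.906,1.6051,-0.18
14,112598-30-8,0.40,1.69,2.16,2.070,2.0043,-0.66
15,7120-01-6,0.75,0.80,1.00,1.305,1.1382,-0.04
16,104076-38-2,0.40,1.38,2.64,2.689,2.9946,0.14
17,104076-32-6,0.40,1.40,2.69,2.694,2.8898,0.22
18,133099-04-4,0.49,1.58,2.82,2.800,2.2978,-0.62
19,142494-12-0,0.00,1.73,1.83,1.490,2.6577,0.16
20,486-56-6,0.00,1.38,1.49,1.049,1.3867,0.04
21,54-11-5,0.00,1.08,0.92,0.865,1.3710,0.56
22,494-97-3,0.13,0.85,1.02,0.990,1.2301,0.32
23,58-08-2,0.05,1.28,1.72,1.500,1.3632,0.01
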