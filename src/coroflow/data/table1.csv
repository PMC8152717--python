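case,artery,pa_bl,pd_bl,dp_bl,pdpa_bl,q_bl,mvr_bl,sr_bl,pa_hyp,pd_hyp,dp_hyp,ffr,q_hyp,mvr_hyp,sr_hyp,pct_delta_mvr,pct_delta_sr,pct_delta_q,cfr_dop,cfr_qcfd,cfr_pd,venous_pressure_mmHg
1,LAD,88.0,79.4,8.7,0.90,22.7,3.49,0.38,78.0,61.0,17.0,0.78,35.8,1.70,0.47,-51,24,58,1.8,1.58,1.40,0
2,LAD,92.7,85.6,7.1,0.92,67.7,1.26,0.10,75.7,61.5,14.2,0.81,109.2,0.56,0.13,-56,30,61,1.3,1.61,1.41,0
3,RCA,106.3,99.6,6.7,0.94,89.8,1.11,0.08,83.5,71.3,12.2,0.85,165.3,0.43,0.07,-61,-13,84,2.1,1.84,1.35,0
4,LAD,119.9,114.7,5.1,0.96,72.9,1.57,0.07,114.9,91.7,23.1,0.80,193.0,0.48,0.12,-69,71,165,2.4,2.65,2.13,0
5,RCA,89.1,66.4,22.7,0.74,93.2,0.71,0.24,88.3,53.8,34.5,0.61,121.9,0.44,0.28,-38,17,31,1.5,1.31,1.23,0
6,LCX,74.3,69.1,5.2,0.93,36.6,1.89,0.14,77.4,60.0,17.5,0.77,88.7,0.68,0.20,-64,43,142,1.1,2.42,1.83,0
7,LAD,76.7,51.8,24.9,0.68,89.0,0.58,0.28,65.2,33.1,32.2,0.51,105.4,0.31,0.31,-47,11,19,1.1,1.19,1.14,0
8,LAD,99.0,80.9,18.1,0.82,75.4,1.07,0.24,104.6,73.6,31.0,0.70,108.9,0.68,0.28,-36,17,44,1.5,1.44,1.31,0
9,LAD,96.4,87.6,8.8,0.91,36.6,2.40,0.24,71.4,62.7,8.7,0.88,36.3,1.73,0.24,-28,0,-1,2.40,0.99,0.99,0
10,LAD,117.3,112.9,4.4,0.96,23.5,4.80,0.19,102.3,89.0,13.3,0.87,52.8,1.69,0.25,-65,32,125,2.07,2.25,1.74,0
11,RCA,90.0,88.0,1.9,0.98,41.3,2.13,0.05,75.0,67.6,7.4,0.90,102.5,0.66,0.07,-69,40,148,1.90,2.48,1.97,0
12,RCA,112.1,59.4,52.7,0.53,115.1,0.52,0.46,118.8,62.2,56.5,0.52,119.7,0.52,0.47,0,2,4,1.18,1.04,1.04,0
13,LAD,112.6,106.9,5.7,0.95,58.0,1.84,0.10,110.4,103.4,7.0,0.94,66.4,1.56,0.11,-15,10,14,1.38,1.14,1.11,0
14,RCA,106.5,105.8,0.7,0.99,29.7,3.56,0.02,103.7,102.0,1.7,0.98,60.1,1.70,0.03,-52,50,102,2.42,2.02,1.56,0
15,LAD,99.6,80.3,19.3,0.81,46.4,1.73,0.42,97.0,69.9,27.1,0.72,58.2,1.20,0.47,-31,12,25,1.61,1.25,1.18,0
16,LAD,109.9,92.9,17,0.85,86.8,1.07,0.20,103.1,86.1,17.0,0.84,86.7,0.99,0.20,-7,0,0,1.67,1.00,1.00,0
17,LAD,110.3,98.4,11.9,0.89,55.6,1.68,0.21,106.4,85.0,21.4,0.80,79.1,1.01,0.27,-40,29,42,1.2,1.42,1.34,5
18,LCX,108.1,94.5,13.6,0.87,85.0,1.05,0.16,113.7,88.5,25.2,0.78,121.2,0.69,0.21,-34,31,43,2,1.43,1.36,5
19,LAD,96.4,87.6,8.8,0.91,84.1,0.98,0.10,71.5,62.4,9.1,0.87,85.2,0.67,0.11,-32,10,1,F,1.01,1.02,5
20,LAD,106.3,99.6,6.7,0.94,67.6,1.40,0.10,81.8,63.6,18.2,0.78,123.5,0.47,0.15,-66,50,83,F,1.83,1.65,5
21,LAD,88.6,79.5,9.1,0.90,27.1,2.75,0.34,80.9,58.9,22.0,0.73,47.7,1.13,0.46,-59,35,76,,1.76,1.55,5
22,LAD,74.4,49.5,24.9,0.67,56.2,0.83,0.44,65.0,32.9,32.1,0.51,65.8,0.43,0.49,-48,11,17,,1.17,1.14,5
23,LCX,73.6,68.3,5.3,0.93,38.7,1.64,0.14,79.1,60.8,18.3,0.77,81.6,0.68,0.22,-59,57,111,,2.11,1.86,5
24,LAD,96.3,87.5,8.8,0.91,41.0,2.01,0.21,71.5,62.4,9.1,0.87,41.1,1.40,0.22,-30,5,0,,1.00,1.02,5
25,LAD,99.0,80.9,18.1,0.82,57.4,1.32,0.32,104.4,73.5,30.9,0.70,79.8,0.86,0.39,-35,22,39,,1.39,1.31,5
26,LAD,119.0,112.1,6.9,0.94,42.0,2.55,0.16,103.4,88.5,14.9,0.86,62.6,1.33,0.24,-48,50,49,,1.49,1.47,5
27,LAD,112.3,106.7,5.6,0.95,61.5,1.65,0.09,122.0,113.1,8.9,0.93,82.2,1.32,0.11,-20,22,34,,1.34,1.26,5
28,LAD,99.6,80.3,19.3,0.81,47.3,1.59,0.41,95.5,68.7,26.8,0.72,58.8,1.09,0.46,-31,12,24,,1.24,1.18,5
29,LMS,78.8,64.7,14.1,0.82,169.4,0.35,0.08,75.3,47.4,27.9,0.63,257.4,0.16,0.11,-54,38,52,,1.52,1.41,5
30,LAD,87.0,82.1,4.9,0.94,43.4,1.78,0.11,84.1,70.9,13.2,0.84,79.5,0.83,0.17,-53,55,83,,1.83,1.64,5
31,LAD,81.5,73.0,8.5,0.90,44.1,1.54,0.19,78.3,58.2,20.1,0.74,78.2,0.68,0.26,-56,37,77,,1.77,1.54,5
32,LAD,101.6,84.4,17.2,0.83,38.2,2.08,0.45,82.5,48.2,34.3,0.58,59.7,0.72,0.57,-65,27,56,,1.56,1.41,5
33,LAD,93.5,86.3,7.2,0.92,79.4,0.97,0.12,87.0,62.0,25.0,0.71,148.7,0.38,0.17,-61,42,87,,1.87,1.86,5
34,LAD,109.0,102.0,7.0,0.94,52.4,1.85,0.13,118.8,110.2,8.6,0.93,59.0,1.78,0.15,-4,15,13,,1.13,1.11,5
35,LCX,130.4,119.4,11.0,0.92,79.6,1.44,0.14,118.0,101.0,17.0,0.86,105.2,0.91,0.16,-37,14,32,,1.32,1.24,5
36,LCX,94.2,84.9,9.3,0.90,83.4,0.96,0.11,96.7,67.6,29.1,0.70,173.8,0.36,0.17,-63,55,108,,2.08,1.77,5
37,LAD,99.7,90.5,9.2,0.91,75.1,1.14,0.12,98.2,84.8,13.4,0.86,92.5,0.86,0.14,-25,17,23,,1.23,1.21,5
38,LAD,88.0,82.6,5.4,0.94,66.8,1.16,0.08,78.7,58.6,20.1,0.74,138.1,0.39,0.15,-66,88,107,,2.07,1.93,5
39,LAD,67.1,59.8,7.3,0.89,50.4,1.09,0.14,69.8,59.4,10.4,0.85,63.7,0.85,0.16,-22,14,26,,1.26,1.19,5
40,LAD,69.8,64.4,5.4,0.92,49.7,1.20,0.11,66.0,56.1,9.9,0.85,73.9,0.69,0.13,-43,18,49,,1.49,1.35,5
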