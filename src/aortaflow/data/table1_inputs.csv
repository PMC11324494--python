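symbol,base60,s60_119.1_79.8,s60_109.1_79.8,s60_99.1_79.8,s60_109.1_69.8,s60_99.1_69.8,base80,s80_144_76,s80_134_76,s80_124_76,s80_114_76,s80_134_66,s80_124_66,s80_114_66
Ps,129.1,119.1,109.1,99.1,109.1,99.1,154,144,134,124,114,134,124,114
Pd,79.8,79.8,79.8,79.8,69.8,69.8,76,76,76,76,76,66,66,66
lam_z,1.08,1.08,1.08,1.08,1.08,1.08,1.01,1.01,1.01,1.01,1.01,1.01,1.01,1.01
eps_Ap,0.015,0.015,0.015,0.015,0.015,0.015,0.01,0.01,0.01,0.01,0.01,0.01,0.01,0.01
Dso,35.4,35.4,35.4,35.4,35.4,35.4,35.9,35.9,35.9,35.9,35.9,35.9,35.9,35.9
hs,1.41,1.41,1.41,1.41,1.41,1.41,1.42,1.42,1.42,1.42,1.42,1.42,1.42,1.42
Ds,32.6,32.6,32.6,32.6,32.6,32.6,33.1,33.1,33.1,33.1,33.1,33.1,33.1,33.1
Ddo,34.32,34.32,34.32,34.32,34.32,34.32,33.92,33.92,33.92,33.92,33.92,33.92,33.92,33.92
hd,1.46,1.46,1.46,1.46,1.46,1.46,1.51,1.51,1.51,1.51,1.51,1.51,1.51,1.51
Dd,31.4,31.4,31.4,31.4,31.4,31.4,30.9,30.9,30.9,30.9,30.9,30.9,30.9,30.9
E,0.7,0.7,0.7,0.7,0.7,0.7,1.4,1.4,1.4,1.4,1.4,1.4,1.4,1.4
phi,0.038,0.0435,0.0435,0.0435,0.0435,0.0435,0.0425,0.0425,0.0425,0.0425,0.0425,0.0425,0.0425,0.0425
Re,909.09,909.09,909.09,909.09,909.09,909.09,833,833,833,833,833,833,833,833
n,66.1,66.1,66.1,66.1,66.1,66.1,67,67,67,67,67,67,67,67
beta,1.24,1.24,1.24,1.24,1.24,1.24,2.91,3.01,3.01,3.01,3.01,3.01,3.01,3.01
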