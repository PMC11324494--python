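symbol,base60,s60_119.1_79.8,s60_109.1_79.8,s60_99.1_79.8,s60_109.1_69.8,s60_99.1_69.8,base80,s80_144_76,s80_134_76,s80_124_76,s80_114_76,s80_134_66,s80_124_66,s80_114_66
P,96.2,92.9,89.6,86.2,82.9,79.6,102,98.7,95.3,92,88.7,88.7,85.3,82
V,0.123,0.119,0.104,0.088,0.118,0.104,0.119,0.111,0.103,0.096,0.087,0.110,0.103,0.094
Q,0.096,0.093,0.082,0.069,0.092,0.081,0.09,0.084,0.078,0.072,0.066,0.083,0.078,0.072
Qbar,6.37,6.16,5.43,4.58,6.11,5.38,6.06,5.62,5.25,4.84,4.41,5.58,5.20,4.79
CBF_lo,765,739,652,550,733,645,727,675,630,581,528,670,624,575
CBF_hi,956,924,814,688,917,806,908,844,787,727,660,837,780,719
delta_pct,,-3.33,-14.79,-28.05,-4.08,-15.65,,-7.11,-13.32,-20.01,-27.32,-7.86,-14.12,-20.88
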