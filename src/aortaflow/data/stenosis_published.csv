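degree_pct,area_ratio,delta_cbf_pct
0,1.0,0.0
50,0.50,-41.8
70,0.374,-51.0
80,0.312,-55.2
90,0.252,-61.8
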