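# Least-squares fit of the dissipation shape coefficient K to the
# published beta values of the bundled reference table (see
# aortaflow.calibration.fit_K_table). Regenerate with:
#   aortaflow calibrate --out src/aortaflow/data/calibration.yaml
K_hat: 0.827276496205797
K_hat_60y: 0.8059946959447425
K_hat_80y: 0.8454480093233265
columns_used:
- base60
- s60_119.1_79.8
- s60_109.1_79.8
- s60_99.1_79.8
- s60_109.1_69.8
- s60_99.1_69.8
- base80
- s80_144_76
- s80_134_76
- s80_124_76
- s80_114_76
- s80_134_66
- s80_124_66
- s80_114_66
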