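# aortaflow

A closed-form fluid–structure model of blood flow through the ascending
aorta, for quantifying how orthostatic hypotension (OH), arterial aging and
carotid stenosis change systemic perfusion (SP) and cerebral blood flow
(CBF). It is aimed at cardiovascular-biomechanics and physiological-modelling
work where a transparent analytical estimate from clinically measurable
parameters is wanted instead of a waveform or Windkessel simulation.

## The model

The pre-stretched elastic aortic wall stores strain energy between diastole
and systole and releases it to drive flow. With α<sub>s</sub> = D<sub>s</sub>/h<sub>s</sub>,
α<sub>d</sub> = D<sub>d</sub>/h<sub>d</sub> (inner diameter over wall thickness at
systole/diastole), constraint coefficient φ and circumferential modulus *E*,
the strain-energy density increment is

> Δu = φ² (α<sub>s</sub> p<sub>s</sub> − α<sub>d</sub> p<sub>d</sub>)² / 8E   [J/m³]

Friction and wall-shear losses enter through the laminar friction factor
λ = 64/Re and a coupled energy-dissipation coefficient

> β = 4 E λ K² (h<sub>d</sub> − h<sub>s</sub>) / (D (p<sub>s</sub> − p<sub>d</sub>) φ)

where *K* is a dimensionless shape coefficient recovered by calibration
(`aortaflow.calibration`). The characteristic velocity (flow distance per
unit weight of blood per stroke), stroke flow and mean flow follow as

> V = λ<sub>z</sub> √( φ h (α<sub>s</sub> p<sub>s</sub> − α<sub>d</sub> p<sub>d</sub>) / (D γ (1 + β)) ),
> Q = (1 + φ D P/(E h)) A<sub>f</sub> V,  Q̄ = n Q

with λ<sub>z</sub> the axial pre-stretch ratio (which declines with age),
γ = ρg the specific weight of blood, P = (2p<sub>d</sub> + p<sub>s</sub>)/3 the
mean pressure, A<sub>f</sub> = πD<sub>d</sub>²/4 the flow area and *n* the pulse
rate. CBF is reported as the 12–15% of systemic perfusion carried by the
carotid arteries. Compliance and the circumferential modulus of a vessel
segment come from the thin-wall relations C = πl(D<sub>s</sub>² − D<sub>d</sub>²)/4PP
and E = D P D<sub>o</sub> / (2h(D<sub>s</sub> − D<sub>d</sub>)), which also power the
stretch-inflation experiment analysis in `aortaflow.inflation`.

All equations are closed form; units at the API are clinical
(mmHg, mm, MPa), SI inside. See `docs/methods.md` for conventions,
assumptions and numerical choices.

## Worked example

A 60-year-old baseline of 129.1/79.8 mmHg:

```bash
$ aortaflow flow --ps 129.1 --pd 79.8 --preset 60y
{
  "ps_mmHg": 129.1, "pd_mmHg": 79.8, "pmean_mmHg": 96.2,
  "V_m": 0.123, "Q_L_per_beat": 0.097, "n_bpm": 66.1,
  "Qbar_L_per_min": 6.39, "CBF_mL_per_min": [766, 957],
  "beta": 1.24, "sedi_J_per_m3": 7.376
}
```

Mean systemic perfusion is 6.39 L/min, of which 766–957 mL/min reaches the
brain. A 30 mmHg orthostatic systolic drop against the same baseline:

```bash
$ aortaflow scenario --baseline 60y --dsbp 30
          60y-30/0
Ps            99.1
Pd            79.8
...
Qbar           4.6
CBF        552~690
delta_pct   -27.94
```

i.e. perfusion falls by ~28% and the CBF band drops to 552–690 mL/min —
the quantitative footprint of a severe OH episode. Other entry points:
`aortaflow table1` (full reference grid reproduction + validation),
`aortaflow stenosis` (carotid flow-area reduction, both modes, with
residuals against the published values), `aortaflow calibrate` (fit of K),
and `aortaflow experiment synth|analyze` (synthetic stretch-inflation
records and their compliance/modulus/strain-energy analysis). The same
functionality is available as a library (`import aortaflow`).

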