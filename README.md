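# pvloopva

Closed-loop cardiovascular simulation and pressure-volume (PV) loop analysis
of graded arterial stiffening — the hemodynamic signature of vascular aging.

As the aorta stiffens with age its equivalent compliance `C_A` falls and the
total peripheral resistance `R_T` rises. This package reproduces, entirely in
silico, the classic invasive protocol used to quantify what that does to the
left ventricle: right-atrial pacing under autonomic blockade, a vena caval
occlusion (VCO) that transiently starves the heart of preload, and
least-squares fits of the linear PV relations over the resulting beat family.
It is written for cardiovascular modellers and physiologists who want a
tested, scriptable stand-in for a PV-loop animal study.

## The model and the statistics it produces

The circulation is a lumped-parameter closed loop: four time-varying
elastance chambers, `P(t) = E(t) (V − V0)` with a double-raised-cosine
activation between `E_min` and `E_max`; ideal-diode valves; a proximal
aortic-arch Windkessel element feeding a systemic-artery node and five
parallel distal beds (coronary, cerebral, skeletal muscle, splanchnic,
extrasplanchnic); systemic and thoracic venous pools; and a two-compartment
pulmonary loop. Each state is a blood volume and each derivative an
inflow-outflow balance, so total blood volume is conserved exactly. The VCO
is a time-based ramp of the thoracic-vein outflow resistance.

From each occlusion run the analysis layer measures every standard PV scalar
(EDV, ESV, SV, SW, Pes, LVEDP, PP, dP/dt_max) and fits, by ordinary least
squares over the declining-preload beats:

- **ESPVR** — `Pes = E_es (ESV − V0)`, end-systolic elastance (contractility);
- **PRSW** — `SW = M_w (EDV − V_w)`, preload recruitable stroke work;
- **dP/dt_max–EDV** — slope `dE/dt_max`;
- **PVA–EDV** — slope of the pressure-volume area, `PVA = SW + ½ Pes (ESV − V0)`
  (Suga's total mechanical energy, a proxy for myocardial oxygen demand);

plus **mechanical efficiency** `ME = 100·SW/PVA` and **dynamic arterial
compliance** `Art-ca = SV/Pes`.

Two study drivers are packaged: phase 1 sweeps five `(C_A, R_T)` settings
from normal (0.70, 1.28) to stiff (0.19, 3.66) at 80 bpm; phase 2 paces the
normal and stiff settings at 60, 100 and 140 bpm.

## Worked example

```sh
python examples/01_baseline_waveforms.py
```

```
converged: True after 20 beats (15.0 s)
aortic pressure      :  120.2 /  78.6 mmHg (pulse 41.6 mmHg)
LV volumes           : EDV   98.8 ml, ESV  42.2 ml, SV 56.6 ml
LV end-diastolic P   :   7.95 mmHg
peak dP/dt           :   1830 mmHg/s
```

The normal configuration settles at the textbook adult operating point:
~120/79 mmHg aortic pressure with a ~42 mmHg pulse and an end-diastolic
volume near 100 ml. Fitting the occlusion relations
(`python examples/02_vco_relations.py`) recovers the configured end-systolic
elastance from the simulated data:

```
occlusion family      : 11 beats
ESPVR slope           : 2.98 mmHg/ml (configured E_max 3.00), V0 5.0 ml, r^2 1.0000
PRSW slope            : 93.0 mmHg
dP/dt_max-EDV slope   : 24.7 mmHg/s/ml
PVA-EDV slope         : 123.6 mmHg
mechanical efficiency : 73.2 % (steady beat)
```

`examples/03_vascular_aging_phase1.py` and `04_rate_effects_phase2.py` run
the full study sweeps and report trend agreement with the published tables
(volumes, stroke work and pulse pressure rise with stiffening while
efficiency and dynamic compliance fall; rate raises ESPVR and the
dP/dt_max–EDV slope while volumes, PRSW and efficiency fall);
`05_synthetic_families.py` exercises the analysis layer on generated beat
families with known ground truth.

A thin CLI wraps the same calls:

```sh
pvloop-va run --phase 1 --out out/          # study tables + trajectories
pvloop-va analyze --input ts.csv --hr 80 --out out/
pvloop-va fixtures --seed 7 --out out/
pvloop-va compare --phase 1 --table out/phase1_table.csv
```

## Layout

- `src/pvloopva/config.py` — chamber/vascular parameters, defaults, YAML I/O
- `src/pvloopva/elastance.py` — activation waveforms, pacing clock
- `src/pvloopva/circuit.py` — the ODE network, integration, steady-state driver
- `src/pvloopva/protocols.py` — compliance settings, VCO, phase 1/2 drivers
- `src/pvloopva/beats.py`, `relations.py` — segmentation, metrics, OLS fits
- `src/pvloopva/fixtures.py` — synthetic beats/families with known truth
- `src/pvloopva/reference.py` — packaged published tables, trend comparison
- `docs/methods.md` — model equations, assumptions, calibration rationale
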