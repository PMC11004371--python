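# Methods

## Model structure

The circulation is a closed loop of 15 volume states: four elastance
chambers (left/right atria and ventricles) and eleven passive vascular
compartments — aortic arch, systemic artery, five parallel distal systemic
beds (coronary, cerebral, skeletal muscle, splanchnic, extrasplanchnic),
systemic vein, thoracic vein, pulmonary artery and pulmonary vein. Every
compartment obeys `P = (V − V_u)/C`; every chamber obeys
`P = E(t)(V − V0)`, clamped below at −5 mmHg so deep preload reduction
cannot produce unphysical suction. Resistive elements connect neighbours;
the four valves are ideal diodes (flow `max(ΔP, 0)/R_open`, no inertance,
open resistances 5 mΩ-equivalent aortic/pulmonic and 3 mitral/tricuspid in
mmHg·s/ml). Each state derivative is inflow minus outflow, so the sum of all
derivatives is identically zero and total blood volume (default 5300 ml) is
conserved to solver precision.

Units are mmHg, ml and s throughout. The model runs under autonomic
blockade: there is no reflex loop, and the flag cannot be disabled.

## Activation waveform and timing

Activation rises from 0 to 1 over the systolic interval as a raised cosine
taken to the power 0.42 (brisk early contraction, smooth peak at
end-systole) and relaxes as a half raised cosine over half the systolic
interval. Systolic duration follows a Bazett-like rule
`T_sys = 0.54·sqrt(60/HR)` seconds, capped at 0.62 of the cycle; at 80 bpm
systole lasts ≈ 0.40 s. Atrial activation uses the same shape, 0.10 s long,
leading ventricular onset by 0.16 s (the atrial kick that sets a physiologic
LV end-diastolic pressure). The force-frequency relation is an explicit
linear gain on ventricular `E_max`: `1 + 0.3 (HR − 80)/80`.

## Calibration of the normal configuration

The normal setting must express equivalent arterial compliance
`C_A = 0.70 ml/mmHg` and total peripheral resistance `R_T = 1.28 mmHg·s/ml`
while producing the textbook ~120 mmHg systolic / ~40 mmHg pulse aortic
waveform at 80 bpm. Those pressures are demanding at so low a `C_A`: the
Windkessel time constant `C_A·R_T ≈ 0.9 s` forces a fast diastolic decay, so
the diastolic window must be short and the aortic valve must close near peak
pressure. Three linked choices follow, all fixed before the study sweeps:

- the aortic arch holds most of the compliance (0.64 of 0.70; the lumped
  systemic artery 0.036 and the five distal beds 0.024 together, i.e. the
  distal beds are near-rigid pressure nodes), so the arch decay sees nearly
  the full time constant rather than a faster local one;
- systole is long (0.40 s at 80 bpm) with a steep onset, shortening both the
  isovolumic delay and the diastolic runoff window;
- ventricular `E_max = 3.0 mmHg/ml` with `V0 = 5 ml`, which closes the valve
  near 115–120 mmHg.

With preload set by the venous unstressed volume (systemic vein 2490 ml,
compliance 80 ml/mmHg), the settled beat gives 120.2/78.6 mmHg (pulse
41.6 mmHg), EDV 98.8 ml and dP/dt_max ≈ 1.8·10³ mmHg/s. A consequence
accepted deliberately: the fitted ESPVR of the normal run is ≈ 3.0 mmHg/ml
and end-systolic pressure ≈ 111 mmHg, higher than some published in-vivo
values for a normal ventricle; the published steady-state table this package
mirrors is itself not simultaneously satisfiable with the 120/40 target at
the printed `(C_A, R_T)`, and the directional behaviour across conditions —
the object of the study — is unaffected.

`R_T` is defined as the proximal arch+artery resistance in series with the
parallel reduction of the five distal branches (feed plus outflow); venous
and pulmonary resistances sit outside it. Distal branch conductances are
weighted by typical regional flow fractions (coronary 5%, cerebral 14%,
muscle 17%, splanchnic 44%, extrasplanchnic 20%).

## Stiffening and the occlusion

A compliance setting retargets the arterial tree by one common factor on
all seven arterial compliances and one on all arterial resistances, hitting
the target `(C_A, R_T)` exactly while preserving the proximal/distal split;
the operation is idempotent. The five packaged settings are (0.70, 1.28),
(0.63, 1.41), (0.56, 1.54), (0.42, 1.805) and (0.19, 3.66).

The VCO multiplies the thoracic-vein outflow resistance — the venous return
path into the right atrium, downstream of the systemic-vein pool — by 100×
over an 8 s geometric ramp, after the loop has settled. Beats are harvested
from the last steady beat (the "first beat of the occlusion" by the
steady-state sampling convention) until EDV has fallen by 40% of its steady
value or 12 s elapse; with these defaults the family holds ~9–25 beats
depending on rate, the size range of in-vivo occlusion fits. The first
occlusion beat is included in fits by default (configurable).

## Analysis definitions

- End-diastole is the pacing-onset sample; EDV and LVEDP are read there.
- ESV is the minimum volume of the beat.
- Pes is LV pressure at aortic valve closure (last sample with positive
  aortic valve flow); when no flow trace exists (external CSV input) it
  falls back to pressure at minimum volume.
- dP/dt_max uses a centred finite difference at the 1 kHz resample, no
  smoothing.
- SW is the shoelace area of the (V, P) polygon; an open loop (first/last
  samples differing by > 2 ml or > 5 mmHg) is closed with a warning.
- PVA = SW + ½·Pes·(ESV − V0) with V0 from the ESPVR fit of the same run
  (fit first, then per-beat PVA); the area under the end-diastolic PV
  relation is neglected, the standard Suga simplification. ME = 100·SW/PVA.
- All four relation fits are unweighted ordinary least squares; the volume
  intercept is −intercept/slope.

## Numerical choices

LSODA (stiff-capable) with `rtol = atol = 1e−6`, a 1 ms step ceiling and
1 kHz output resampling, chosen so dP/dt_max is resolved. Steady state is
declared when EDV, ESV and mean aortic pressure each vary < 0.5%
(peak-to-peak, relative) over 5 consecutive beats, with a 180 s cap;
non-convergence is recorded on the result, not fatal. Study sweeps run in
tens of seconds on one CPU; trajectories restart across segment boundaries
phase-locked to the absolute pacing clock.

## Synthetic data

The fixture generators emulate the *structure* the analysis assumes, not the
simulator's physics: occlusion families whose Pes, SW, dP/dt_max and PVA lie
exactly on four specified lines (ESV derived consistently from the Suga
decomposition), with optional seeded Gaussian noise of SD = fraction ×
value on each metric; a rectangular PV loop with exact analytic area; and a
single-chamber ejection into a two-element RC afterload for the elastance
identity. Passing fixture tests therefore shows the estimators are correct
on data meeting their assumptions; it does not validate the circulatory
model itself, and no fixture reproduces measurement artifacts (catheter
whip, drift) of real laboratory data.

## Known limitations

No wave reflection, pulse-wave velocity or vessel inertance; no
baroreflex/chemoreflex; no lung mechanics or gas transport; no regional wall
mechanics. The force-frequency gain is a documented knob, not an emergent
property. Absolute steady-state values (especially Pes and the relation
slopes) carry the calibration compromise described above; directional
comparisons across compliance and rate are the intended use.
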