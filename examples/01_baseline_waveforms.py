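"""Settle the normal configuration at 80 bpm and report the classic
hemodynamic vitals of the last steady beat.

The aortic trace should show the textbook ~120/80 mmHg adult waveform with a
~40 mmHg pulse, and the left ventricle an end-diastolic volume near 100 ml.
"""

import numpy as np

from pvloopva import default_config, run_to_steady_state

config = default_config(heart_rate=80.0)
ts, state = run_to_steady_state(config)
print(f"converged: {ts.steady_state.converged} "
      f"after {ts.steady_state.n_beats} beats ({ts.steady_state.duration:.1f} s)")

beat = ts.time >= ts.time[-1] - config.beat_period + 1e-9
p_ao, p_lv, v_lv = ts.p_ao[beat], ts.p_lv[beat], ts.v_lv[beat]
dpdt = np.max(np.gradient(p_lv, ts.time[beat]))

print(f"aortic pressure      : {p_ao.max():6.1f} / {p_ao.min():5.1f} mmHg "
      f"(pulse {p_ao.max() - p_ao.min():.1f} mmHg)")
print(f"LV volumes           : EDV {v_lv[0]:6.1f} ml, ESV {v_lv.min():5.1f} ml, "
      f"SV {v_lv[0] - v_lv.min():.1f} ml")
print(f"LV end-diastolic P   : {p_lv[0]:6.2f} mmHg")
print(f"peak dP/dt           : {dpdt:6.0f} mmHg/s")
print("Systolic/diastolic aortic pressure and stroke volume define the "
      "operating point every later experiment perturbs.")
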