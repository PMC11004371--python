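"""Generate a synthetic occlusion beat family with known linear structure
and show that the relation fits recover the ground truth, with and without
measurement noise.

This exercises the analysis layer completely independently of the ODE
simulator: the generator writes beats that lie exactly on four specified
lines, optionally jittered by seeded Gaussian noise.
"""

from pvloopva import FixtureSpec, fit_espvr, fit_prsw, fit_pva_edv, make_vco_family

truth = FixtureSpec(espvr_slope=1.8, v0=15.0, prsw_slope=75.0, vw=20.0,
                    pva_slope=92.0, v_pva=25.0)

clean = make_vco_family(truth)
noisy = make_vco_family(FixtureSpec(noise_sd_fraction=0.02, seed=42))

print(f"{'relation':10s} {'truth':>8s} {'clean fit':>10s} {'2% noise fit':>13s}")
for name, target, fit in [("ESPVR", 1.8, fit_espvr), ("PRSW", 75.0, fit_prsw),
                          ("PVA-EDV", 92.0, fit_pva_edv)]:
    print(f"{name:10s} {target:8.2f} {fit(clean).slope:10.4f} {fit(noisy).slope:13.3f}")

print("Clean fits reproduce the generating slopes to numerical precision; "
      "2% noise perturbs them by a few percent, the scale of scatter seen "
      "in real occlusion data.")
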