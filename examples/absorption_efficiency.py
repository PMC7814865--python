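"""Microwave-absorption efficiency vs sucrose concentration.

Generates a synthetic constant-power absorption study (5/10/15/20 % w/v
sucrose at 0/540/1080/1600 W for 1 h), converts the water removed per vial
to absorbed power via the enthalpy of sublimation, subtracts the
zero-power background, fits absorbed-vs-applied lines per concentration,
and regresses the fitted efficiency on concentration.  The per-vial
power-ratio slope rises linearly with solute content: more dissolved
sucrose couples more microwave energy into the product.
"""

from mvdry.absorption import AbsorptionRun, analyze_absorption_study
from mvdry.synthetic import AbsorptionStudySpec, gen_absorption_study

spec = AbsorptionStudySpec(seed=7)
runs = [AbsorptionRun(r.sucrose_pct_wv, r.applied_power_W, r.duration_h,
                      int(r.n_vials), r.mass_removed_g_per_vial)
        for r in gen_absorption_study(spec).itertuples()]
fits, (gradient, intercept, r2) = analyze_absorption_study(runs)

print("per-concentration absorbed-vs-applied fits (per-vial power ratio):")
for fit in fits:
    print(f"  {fit.sucrose_pct_wv:4.0f}% w/v: slope {fit.raw_power_ratio_slope:.3e}"
          f"  r^2 {fit.r_squared:.4f}")
print(f"efficiency vs concentration: gradient {gradient:.3e} per % w/v, "
      f"r^2 {r2:.3f}")
print(f"generator truth: {spec.true_per_vial_slope():.3e} per % w/v")
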