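"""Microwave cycle schedules: power lookup, energy exposure, cycle-time math.

Loads the benchmark full microwave cycle (five constant-power steps, 360
min of exposure), integrates the energy delivered to a partial run, and
shows the fractional-cycle-time normalization used to compare partial
microwave and lyophilizer runs, plus the headline cycle-time reductions.
"""

from mvdry import (fractional_cycle_time, load_builtin_cycle,
                   percent_reduction, power_at, total_energy_exposure)

cycle = load_builtin_cycle("mvd_full")
print(f"cycle '{cycle.name}': {len(cycle.steps)} steps, "
      f"{cycle.total_duration_min:.0f} min of exposure")
for t in (10, 100, 250, 330):
    print(f"  power at t={t:>3d} min: {power_at(cycle, t):6.0f} W")
print(f"energy in first 90 min (quarter run): "
      f"{total_energy_exposure(cycle, 90):.2f} kWh")
print(f"energy over the whole exposure: {total_energy_exposure(cycle):.2f} kWh")

_, f_mvd = fractional_cycle_time(210, "mvd", full_time_min=370, secondary_hold_min=60)
_, f_lyo = fractional_cycle_time(750, "lyo", convergence_time_min=1120)
print(f"fractional cycle time, microwave run stopped at 210 min: {f_mvd:.2f}")
print(f"fractional cycle time, lyophilizer run stopped at 750 min: {f_lyo:.2f}")
print(f"overall cycle reduction 50 h -> 6.5 h: "
      f"{percent_reduction(50, 6.5):.0f}%")
print(f"primary-drying reduction 18 h -> 3 h: "
      f"{percent_reduction(18, 3):.1f}%")
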