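# Benchmark lyophilization study: 5% w/v sucrose, 0.7 mL fill,
# rectangular 543-vial tray, shelf cycle -50 / -15 / +30 C at 40 mTorr.
mode: lyo
schedule: lyo_benchmark
layout: lyo_rect
convergence_time_min: 1120
geometry:
  outer_area_m2: 2.27e-4
  product_area_m2: 1.767e-4
  fill_volume_ml: 0.7
  inner_diameter_m: 0.015
formulation:
  sucrose_pct_wv: 5.0
heat_transfer:
  Kc: 1.6
  Kg: 1.0
  shelf_emissivity: 0.18
  vial_top_emissivity: 0.84
  shelf_temperature_K: 258.15
  lid_temperature_K: 258.15
mass_transfer:
  R0: 1.4
  A1: 16.0
  A2: 0.0
microwave:
  absorption_efficiency: 0.0
  n_vials_in_chamber: 1
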