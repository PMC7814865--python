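# Benchmark microwave vacuum drying study: 5% w/v sucrose, 0.7 mL fill,
# tight-pack wedges (224 vials), full-power schedule.
mode: mvd
schedule: mvd_full
layout: tight_wedge
full_cycle_time_min: 370
secondary_hold_min: 60
geometry:
  outer_area_m2: 2.27e-4
  product_area_m2: 1.767e-4
  fill_volume_ml: 0.7
  inner_diameter_m: 0.015
formulation:
  sucrose_pct_wv: 5.0
heat_transfer:
  Kc: 0.3
  Kg: 0.2
  shelf_emissivity: 0.0
  vial_top_emissivity: 0.2
  shelf_temperature_K: 293.15
  lid_temperature_K: 293.15
mass_transfer:
  R0: 1.4
  A1: 16.0
  A2: 0.0
microwave:
  absorption_efficiency: 0.12
  n_vials_in_chamber: 224
  self_regulation_gamma: 1.0
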