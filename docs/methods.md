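# Methods

## Scope and model structure

`mvdry` models the primary-drying (sublimation) phase of vial drying only.
Freezing, secondary drying (desorption of unfrozen water), electromagnetic
field distribution inside the cavity, and frequency-dependent dielectric
dispersion are out of scope; schedules may contain secondary-drying
segments but the simulator stops when the ice is exhausted.

The core is a steady-state energy balance per vial. Mass transfer:
`dm/dt = Ap(Pi − Pc)/Rp`, evaluated in the customary Torr·h·cm²/g
resistance system. Heat transfer: shelf conduction lumped into
`Kv = Kc + Kr + Kg` acting on the vial cross-section `Av`, vial-top
radiation `Av·ev·σ(Ti⁴ − T⁴)`, plus a per-vial microwave term. Setting
total heat equal to `ΔHs·dm/dt` (ΔHs = 2840 J/g, treated as constant over
the primary-drying range) yields one equation in the product temperature
`Tp`. The residual is strictly decreasing in `Tp` — heat supply falls while
latent demand rises — so the root is unique whenever it exists.

## Ice vapor pressure

The sublimation line of ice is represented by a single-term
Clausius–Clapeyron correlation `P(Torr) = 2.698×10¹⁰·exp(−6144.96/T)`,
valid on 180–273.16 K. With these defaults the correlation reproduces the
two benchmark interface pressures (187 mTorr at −34 °C, 135 mTorr at
−37 °C) at the package's integer-mTorr reporting convention. The specific
parameterization behind those printed benchmarks is not documented at the
source, so this choice is an inference; the correlation is a replaceable
object (`IceCorrelation`) and any alternative form can be swapped in. The
closed-form inverse `T = B/ln(A/P)` is used for the zero-heat limit and is
round-trip exact to 1e−10 relative.

## Numerical choices

* **Steady-state solver**: Brent root-finding on the fixed bracket
  [180, 273] K (`xtol` near machine precision), followed by a bisection
  polish until the balance residual is below 1e−9 W. Deterministic, no
  randomness. A missing sign change (too little heat, or enough heat to
  push the balance past the melt bracket) raises with both endpoint
  residuals.
* **Time stepping**: quasi-steady, default `dt` = 0.5 min; each step
  solves an instantaneous steady state, decrements the ice mass by
  `rate·dt` and advances the dried layer in proportion to the fraction
  sublimed. No sensible-heat term is carried for the frozen plug. The final
  step is cut exactly at ice exhaustion, so mass is conserved to machine
  precision and the cumulative heat input equals `ΔHs ×` mass sublimed
  identically; a self-convergence test bounds the dt-sensitivity of the
  drying endpoint below 1% between dt = 1 and 0.5 min.
* **Step intervals** in schedules are half-open `[start, end)`; a time on a
  boundary belongs to the later step. Energy exposure integrates the
  piecewise-constant power profile exactly. Reported fractional cycle
  times are rounded half-up to 2 decimals; raw values are retained.
* **Condensation regime** (`Pc > Pi`): the rate law returns negative values
  (flagged), but the simulator clamps mass change at zero — ice growth by
  chamber-vapor deposition is not modelled.

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| ΔHs | 2840 J/g | latent heat of ice sublimation, constant over the range |
| vial | Av = 2.27 cm², Ap = 1.767 cm², 0.7 mL fill | 3-cc ISO 2R tubing vial |
| Rp(l) | R0 = 1.4, A1 = 16, A2 = 0 (Torr·h·cm²/g, l in cm) | typical 5% sucrose cake values from the lyophilization literature; the source analyses treat Rp as a lump, so the thickness dependence is this package's addition for time stepping |
| lyo Kv | Kc = 1.6, Kg = 1.0 W·m⁻²·K⁻¹ | low-pressure (≤ 50 mTorr) gas conduction is weak; with shelf radiation this gives Kv ≈ 3.4, which reproduces an ~18 h primary drying and a −37 °C plateau for the benchmark shelf cycle |
| shelf-radiation coefficient | 4.6 W·m⁻²·K⁻¹ per unit emissivity | the classical 1.1×10⁻⁴ cal·s⁻¹·cm⁻²·K⁻¹ literature value converted to SI; the mixed-unit literature rendering is ambiguous, so it is a config value; default shelf emissivity 0.18 keeps the term below Kc |
| MVD background heat | Kc = 0.3, Kg = 0.2, ev = 0.2, walls at 293 K | no heated shelf in the microwave chamber; reproduces the few-hundredths g/h zero-power background seen in absorption front runs |
| absorption efficiency η | 0.12 (chamber-level), 224 vials | 224 = 7 tight-pack wedges × 32 vials; with the benchmark power schedule this dries a 0.68 g ice load in ~4.6 h |
| self-regulation γ | 1 (absorbed power ∝ remaining ice fraction) | implements the hypothesis that microwave absorption falls as moisture is removed; γ = 0 disables |
| solution density | 1 + 0.0039·(% w/v sucrose) g/mL | linear approximation; all water assumed frozen (no unfrozen-water correction) |

### Fitted-to-data calibration constants

The edge-vial heat multipliers are **descriptive fits**, not predictions:
they were chosen so that the simulated partial runs reproduce the reported
benchmark group means (lyophilizer run stopped at 58% of the cycle: center
≈ 0.60, edge ≈ 0.92 fraction sublimed, giving edge multiplier 1.80 and
inner-edge 1.30; tight-pack microwave run stopped at 70% with chamber
efficiency 0.065: center ≈ 0.76, edge ≈ 0.87, giving edge multiplier 3.2
on the small non-microwave background heat). In MVD mode the multiplier
acts only on the non-microwave input, so large values are needed to move
the edge class — a modelling convenience standing in for extra radiative
view factor and field non-uniformity at the tray perimeter.

## Schedules

The benchmark cycles ship as delimited-text fixtures (five microwave
schedules and two lyophilizer shelf programs). Strict integration of the
benchmark full microwave cycle gives 5.3 kWh over its 360 min of exposure,
while the summary table published for that cycle lists 5.1 kWh and a 6.2 h
total run time; the difference is attributed to non-exposure dead time
(pauses, pump-down) that the schedule object deliberately does not model —
it stores exposure steps only, and the fractional-cycle normalization
takes the full cycle time (default 370 min) as an explicit argument rather
than deriving it. The tray-style "empirical factor" applied when comparing
partial cycles across dryers is exposed as a multiplicative config
parameter, default 1.0, because no value is documented.

## Gravimetric pipeline

Water removed is the pre/post gross-weight difference (tare cancels);
negative values from weighing noise are kept and flagged, not dropped, to
avoid silent bias. Fractions above 1.05 are flagged. The denominator
(initial water mass) is computed from fill volume, density model and water
mass fraction by default, or supplied directly. Location classes: tray
perimeter = *edge*; on the rectangular lyophilizer tray the next ring in =
*inner edge* (vials missing a full 6-neighbor shell), remainder *center*;
microwave wedge trays use edge/center only. The exact 543-vial lyophilizer
tray geometry is not standardized, so the default rectangular grid is
21 × 26 (546 positions) and configurable. Group statistics use the n−1
sample SD and RSD = 100·SD/mean.

## Absorption pipeline

Mass removed per vial per hour converts to absorbed watts via ΔHs.
Exactly one zero-power background run per concentration stratum is
required and subtracted. Applied power is normalized by the dryer shelf
area and absorbed power by the vial surface area — both equipment inputs
with documented placeholder defaults (0.20 m², 2.3×10⁻³ m²) since no
reference values are published — so the normalized slope carries a
shelf/vial area ratio; the raw per-vial power-ratio slope is reported
alongside and is what the efficiency-vs-concentration regression uses.
Fits are ordinary least squares with a free intercept (absorbing residual
leaks); a through-origin variant is not needed for the shipped analyses.

## Synthetic data: what it does and does not show

The generators produce per-vial fractions from truncated normals
(truncation [0, 1.05]) per location class, balance readings with additive
Gaussian weighing noise (0.001 g), linear absorbed-vs-applied power with a
concentration-dependent efficiency and a background leak, and thermocouple
traces as the simulator's temperature series plus i.i.d. sensor noise with
an exponential relaxation to the terminal temperature after ice
exhaustion. They are deterministic per seed (independent substreams per
class). Between-vial SDs are order-of-magnitude choices (0.03–0.05),
since only partial dispersion data are published.

Passing the recovery tests therefore shows that the pipelines are
*unbiased and correctly calibrated estimators of the structure the
generators encode* — linear absorption, class-separated truncated-normal
fractions, additive noise. It does not validate the physics against real
hardware: real heterogeneity is spatially correlated, backgrounds drift,
absorption can saturate, and thermocouple bias is not white. Absolute
primary-drying durations, specific surface areas, activity retentions and
potency losses exist only on real equipment; for these the suite asserts
the model's conservation laws, solver-vs-grid-oracle agreement,
monotonicity (power, resistance, edge heating) and the published
arithmetic identities instead.

## Problem sizes

The shipped analyses are single-vial simulations (≤ 5,800 time steps for
the 2,910-min shelf cycle), 150–224-vial synthetic weighing studies, and
16-run absorption studies — the same scales as the underlying bench
studies; the whole test battery runs in seconds.

## Known limitations

* Microwave coupling is lumped (η per chamber); no field, cavity-mode or
  rotation modelling, so vial-to-vial microwave non-uniformity enters only
  through the calibrated position multipliers.
* `Kg` is pressure-independent by default; a `kg_of_pressure` hook exists
  but no parameterization is shipped.
* The dielectric route (`P_d = K ε tanδ f E²`) is exact as a formula but
  `K` and `E` are rarely known; the empirical η pathway is the default.
* Tg′ is an input to the collapse flag, not predicted from composition.
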