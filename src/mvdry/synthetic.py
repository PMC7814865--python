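"""Seeded generators for every input the analysis pipelines consume.

There is no public dataset behind vial-weighing studies: the raw data are
balance readings and thermocouple traces.  These generators emulate their
statistical structure so the full pipeline — weights in, summary
statistics and fitted efficiencies out — can be exercised and its
estimators validated against known ground truth:

* sublimation studies: per-vial fractions sublimed drawn from truncated
  normals per location class (edge > center heterogeneity, with default
  class means set to the partial-run values reported for the benchmark
  runs), converted back to tare / pre / post balance readings with
  additive weighing noise;
* absorption studies: mass removed per vial growing linearly with applied
  power, with a concentration-dependent efficiency slope, a zero-power
  background leak, and Gaussian noise, truncated at zero;
* thermocouple traces: the deterministic simulator's product-temperature
  series plus i.i.d. Gaussian sensor noise, relaxing exponentially to the
  terminal temperature once the ice is exhausted.

All generators are deterministic under a fixed seed (one root seed per
call; independent substreams per vial via ``numpy.random.default_rng``
spawning).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import simulator as sim
from .gravimetric import RECORD_COLUMNS, TrayLayout, classify_location
from .heat_mass import HeatTransferParams, MassTransferParams, VialGeometry

FRACTION_BOUNDS = (0.0, 1.05)   # weighing noise can push a vial slightly past 1


@dataclass(frozen=True)
class SublimationStudySpec:
    """Spec for a synthetic gravimetric sublimation study.

    Default class means are the benchmark partial-run values (center 59.6%,
    edge 91.8% of water removed for the lyophilizer run stopped at 58%
    completion); they are descriptive calibration constants, not
    predictions.  ``class_means``/``class_sds``/``n_per_class`` share keys.
    """

    class_means: Mapping[str, float] = field(
        default_factory=lambda: {"center": 0.596, "inner_edge": 0.75, "edge": 0.918})
    class_sds: Mapping[str, float] = field(
        default_factory=lambda: {"center": 0.05, "inner_edge": 0.05, "edge": 0.04})
    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"center": 50, "inner_edge": 50, "edge": 50})
    fill_water_mass_g: float = 0.6787    # 0.7 mL of 5% w/v sucrose solution
    fill_solids_mass_g: float = 0.035    # dissolved sucrose, stays in the vial
    tare_mass_g: float = 7.0
    weighing_noise_sd_g: float = 0.001   # analytical balance repeatability
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, mean in self.class_means.items():
            if not FRACTION_BOUNDS[0] <= mean <= FRACTION_BOUNDS[1]:
                raise ValueError(f"class {cls!r} mean {mean} outside "
                                 f"{FRACTION_BOUNDS}")
            if self.class_sds[cls] < 0:
                raise ValueError("SDs must be non-negative")


#: MVD tight-pack benchmark: run stopped at 70% cycle completion
#: (center 76.5%, edge 86.9% of water removed).
MVD_TIGHT_AT_070 = SublimationStudySpec(
    class_means={"center": 0.765, "edge": 0.869},
    class_sds={"center": 0.04, "edge": 0.03},
    n_per_class={"center": 150, "edge": 74},
)


@dataclass(frozen=True)
class AbsorptionStudySpec:
    """Spec for a synthetic microwave-absorption study.

    ``mass_removed = (background_W + efficiency(conc) * applied_W) *
    duration / dHs + noise``, truncated at zero, with
    ``efficiency(conc) = gradient * conc + intercept`` clipped to [0, 1].
    Defaults mirror the benchmark study design: 5/10/15/20 % w/v sucrose at
    0/540/1080/1600 W for 1 h, 19 vials per run.
    """

    concentrations_pct_wv: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    applied_powers_w: tuple[float, ...] = (0.0, 540.0, 1080.0, 1600.0)
    efficiency_gradient_per_pct: float = 0.004    # per-chamber fraction absorbed
    efficiency_intercept: float = 0.04
    n_vials_in_chamber: int = 264                 # 6 loose wedges x 44 vials
    background_w_per_vial: float = 0.05           # zero-power heat leak
    noise_sd_g: float = 0.01
    duration_h: float = 1.0
    n_vials_weighed: int = 19
    dhs_J_per_g: float = 2840.0
    seed: int = 0

    def __post_init__(self) -> None:
        for conc in self.concentrations_pct_wv:
            eff = self.efficiency_at(conc)
            if not 0 <= eff <= 1:
                raise ValueError(f"efficiency {eff:.3f} at {conc}% outside [0, 1]")

    def efficiency_at(self, conc_pct_wv: float) -> float:
        return (self.efficiency_gradient_per_pct * conc_pct_wv
                + self.efficiency_intercept)

    def true_per_vial_slope(self) -> float:
        """Ground-truth gradient of the per-vial power-ratio efficiency
        with concentration (what the pipeline's concentration fit recovers)."""
        return self.efficiency_gradient_per_pct / self.n_vials_in_chamber


@dataclass(frozen=True)
class TraceSpec:
    """Spec for a synthetic product-thermocouple trace."""

    mode: str = "mvd"
    schedule_name: str = "mvd_full"
    noise_sd_K: float = 0.5
    sampling_interval_min: float = 1.0
    relaxation_tau_min: float = 30.0
    terminal_temperature_K: float = 303.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_K < 0:
            raise ValueError("noise_sd_K must be non-negative")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling_interval_min must be positive")


# ---------------------------------------------------------------------------


def _truncnorm_rvs(mean: float, sd: float, size: int, rng: np.random.Generator
                   ) -> np.ndarray:
    lo, hi = FRACTION_BOUNDS
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError(f"degenerate mean {mean} outside {FRACTION_BOUNDS}")
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_sublimation_study(spec: SublimationStudySpec,
                          layout: TrayLayout | None = None) -> pd.DataFrame:
    """Generate vial weighing records with known class-mean fractions.

    Per vial: a fraction sublimed is drawn from the class's truncated
    normal, pre-drying gross = tare + fill mass, and post-drying gross =
    pre - fraction x water mass + weighing noise.  If ``layout`` is given,
    vials are also assigned consistent grid positions (positions of each
    class are drawn from the layout's positions of that class); otherwise a
    synthetic one-row-per-class grid is used.  Returns a frame with
    RECORD_COLUMNS plus true_fraction and location_class.
    """
    rng = np.random.default_rng(spec.seed)
    streams = {cls: s for cls, s in zip(spec.class_means,
                                        rng.spawn(len(spec.class_means)))}
    positions: dict[str, list[tuple[int, int]]] = {}
    if layout is not None:
        for r in range(layout.n_rows if layout.arrangement == "lyo_rect"
                       else len(layout.wedge_rows)):
            ncol = (layout.n_cols if layout.arrangement == "lyo_rect"
                    else layout.wedge_rows[r])
            for c in range(ncol):
                positions.setdefault(classify_location(layout, r, c), []).append((r, c))

    rows = []
    vial_no = 0
    for cls, mean in spec.class_means.items():
        n = spec.n_per_class[cls]
        stream = streams[cls]
        fracs = _truncnorm_rvs(mean, spec.class_sds[cls], n, stream)
        noise = (stream.normal(0.0, spec.weighing_noise_sd_g, n)
                 if spec.weighing_noise_sd_g > 0 else np.zeros(n))
        pos = positions.get(cls)
        if pos is not None and len(pos) < n:
            raise ValueError(f"layout has only {len(pos)} {cls!r} positions "
                             f"for {n} vials")
        for i in range(n):
            row, col = pos[i] if pos is not None else (list(spec.class_means).index(cls), i)
            pre = spec.tare_mass_g + spec.fill_water_mass_g + spec.fill_solids_mass_g
            post = pre - fracs[i] * spec.fill_water_mass_g + noise[i]
            rows.append((f"v{vial_no:04d}", "t01", row, col, spec.tare_mass_g,
                         pre, post, "active", fracs[i], cls))
            vial_no += 1
    return pd.DataFrame(rows, columns=RECORD_COLUMNS + ["true_fraction",
                                                        "location_class"])


def gen_absorption_study(spec: AbsorptionStudySpec) -> pd.DataFrame:
    """Generate absorption-study run records (including background rows).

    Mean mass removed per vial over the run:
    ``(background + efficiency(conc) * applied / n_chamber) * duration *
    3600 / dHs`` plus Gaussian noise on the per-vial mean, truncated at 0.
    Returns a frame with the absorption pipeline's RUN_COLUMNS plus
    ``true_mass_g``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for conc in spec.concentrations_pct_wv:
        eff = spec.efficiency_at(conc)
        for power in spec.applied_powers_w:
            per_vial_w = spec.background_w_per_vial + \
                eff * power / spec.n_vials_in_chamber
            true_mass = per_vial_w * spec.duration_h * 3600.0 / spec.dhs_J_per_g
            noise = rng.normal(0.0, spec.noise_sd_g) if spec.noise_sd_g > 0 else 0.0
            mass = max(0.0, true_mass + noise)
            rows.append((conc, power, spec.duration_h, spec.n_vials_weighed,
                         mass, true_mass))
    return pd.DataFrame(rows, columns=["sucrose_pct_wv", "applied_power_W",
                                       "duration_h", "n_vials",
                                       "mass_removed_g_per_vial", "true_mass_g"])


def gen_thermocouple_trace(spec: TraceSpec,
                           geometry: VialGeometry | None = None,
                           formulation: "sim.Formulation | None" = None,
                           heat_params: HeatTransferParams | None = None,
                           mass_params: MassTransferParams | None = None,
                           mvd_power: "sim.MvdPowerParams | None" = None,
                           ) -> pd.DataFrame:
    """Simulated product-thermocouple trace with sensor noise.

    During primary drying the temperature is the simulator's steady-state
    Tp; after ice exhaustion it relaxes exponentially (time constant
    ``relaxation_tau_min``) toward the terminal temperature.  Returns a
    frame (time_min, temperature_K, noiseless_K).
    """
    from . import config as cfg
    from . import schedules

    geometry = geometry or VialGeometry()
    formulation = formulation or sim.Formulation()
    mass_params = mass_params or MassTransferParams()
    schedule = schedules.load_builtin_cycle(spec.schedule_name)
    if heat_params is None:
        heat_params = (cfg.mvd_default_heat_params() if spec.mode == "mvd"
                       else cfg.lyo_default_heat_params())
    trace = sim.simulate_primary_drying(
        geometry, formulation, heat_params, mass_params, schedule, spec.mode,
        mvd_power=mvd_power, dt_min=min(spec.sampling_interval_min, 0.5))

    t_grid = np.arange(0.0, schedule.total_duration_min + 1e-9,
                       spec.sampling_interval_min)
    tp = np.interp(t_grid, trace.frame.time_min, trace.frame.Tp_K)
    end = trace.primary_drying_end_min
    if end is not None:
        tp_end = float(trace.frame.Tp_K.iloc[-1])
        after = t_grid > end
        tp[after] = spec.terminal_temperature_K + \
            (tp_end - spec.terminal_temperature_K) * \
            np.exp(-(t_grid[after] - end) / spec.relaxation_tau_min)
    rng = np.random.default_rng(spec.seed)
    noise = (rng.normal(0.0, spec.noise_sd_K, t_grid.size)
             if spec.noise_sd_K > 0 else np.zeros(t_grid.size))
    return pd.DataFrame({"time_min": t_grid, "temperature_K": tp + noise,
                         "noiseless_K": tp})
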