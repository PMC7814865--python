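"""Quasi-steady time-stepping simulation of primary drying.

Each time step treats the vial as an instantaneous steady state: the
energy balance of :mod:`mvdry.heat_mass` is solved for the product
temperature and sublimation rate under the current schedule conditions,
the remaining ice mass is decremented, and the dried-layer front advances
in proportion to the fraction sublimed.  No sensible-heat term is carried
for the frozen plug, consistent with a first-order treatment of primary
drying.  The simulator itself is fully deterministic; randomness lives
only in the synthetic-data generators.

Two modes are supported.  ``lyo``: the shelf temperature follows a
:class:`~mvdry.schedules.LyoCycle` and all heat arrives through Kv and top
radiation.  ``mvd``: the applied magnetron power follows a
:class:`~mvdry.schedules.MicrowaveCycle`; each vial absorbs
``applied * efficiency / n_vials`` watts, optionally scaled by the
self-regulation factor ``(m_ice / m_ice,0)**gamma`` which emulates the
hypothesized decline of microwave absorption as residual moisture falls.
With the microwave term zero the mvd path reduces exactly to the
conventional conduction/radiation model.

Position heterogeneity (edge vials drying faster than center vials) is
modelled by a multiplier on the non-microwave heat input per location
class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import schedules
from .heat_mass import (HeatTransferParams, MassTransferParams, VialGeometry,
                        solve_steady_state, with_shelf_temperature)
from .thermo import CONSTANTS, DEFAULT_ICE, IceCorrelation, celsius_to_kelvin

TRACE_COLUMNS = ["time_min", "ice_mass_g", "dried_layer_m", "Tp_K", "fraction_sublimed"]


@dataclass(frozen=True)
class Formulation:
    """Solution composition driving the initial ice load.

    Initial water mass per vial = fill volume x (solution density - solute
    mass per mL), with the density approximated as
    ``1 + 0.0039 * (% w/v sucrose)`` g/mL.  All water is assumed to freeze
    (no unfrozen-water correction).
    """

    sucrose_pct_wv: float = 5.0
    density_slope_per_pct: float = 0.0039

    def density_g_per_ml(self) -> float:
        return 1.0 + self.density_slope_per_pct * self.sucrose_pct_wv

    def water_mass_g(self, fill_volume_ml: float) -> float:
        solids_g_per_ml = self.sucrose_pct_wv / 100.0
        return fill_volume_ml * (self.density_g_per_ml() - solids_g_per_ml)


@dataclass(frozen=True)
class MvdPowerParams:
    """How applied magnetron power maps to per-vial absorbed power."""

    absorption_efficiency: float = 0.12
    n_vials_in_chamber: int = 224   # tight pack: 7 wedges x 32 vials
    self_regulation_gamma: float = 1.0   # 0 disables self-regulation

    def __post_init__(self) -> None:
        if not 0 <= self.absorption_efficiency <= 1:
            raise ValueError("absorption_efficiency must lie in [0, 1]")
        if self.n_vials_in_chamber < 1:
            raise ValueError("n_vials_in_chamber must be >= 1")
        if self.self_regulation_gamma < 0:
            raise ValueError("self_regulation_gamma must be non-negative")


@dataclass(frozen=True)
class PositionModifier:
    """Location-class heat modifier; center vials are the reference class."""

    location_class: str = "center"
    kv_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.kv_multiplier < 1 and self.location_class != "center":
            raise ValueError("non-center kv_multiplier must be >= 1")
        if self.location_class == "center" and self.kv_multiplier != 1.0:
            raise ValueError("center class defines the reference: multiplier must be 1")


#: Default position modifiers. The edge/inner-edge multipliers are
#: calibration constants fitted to the printed partial-run group means
#: (lyophilizer run stopped at fraction 0.58: center 59.6% / edge 91.8%;
#: tight-pack microwave run stopped at 0.70: center 76.5% / edge 86.9%);
#: they are descriptive of those runs, not predictions.
DEFAULT_LYO_MODIFIERS: Mapping[str, PositionModifier] = {
    "center": PositionModifier("center", 1.0),
    "inner_edge": PositionModifier("inner_edge", 1.30),
    "edge": PositionModifier("edge", 1.80),
}
DEFAULT_MVD_MODIFIERS: Mapping[str, PositionModifier] = {
    "center": PositionModifier("center", 1.0),
    "edge": PositionModifier("edge", 3.2),
}
#: Chamber absorption efficiency of the tight-pack partial-run study used
#: for the calibration above; with it the benchmark microwave schedule
#: stopped at 217 min leaves the center class at ~0.76 fraction sublimed.
MVD_TIGHT_STUDY_EFFICIENCY = 0.065


@dataclass
class DryingTrace:
    """Time series of one vial's primary drying plus run metadata."""

    frame: pd.DataFrame
    mode: str
    schedule_name: str = ""
    location_class: str = "center"
    initial_ice_mass_g: float = 0.0
    primary_drying_end_min: float | None = None   # None = ice not exhausted
    heat_input_J: float = 0.0

    @property
    def complete(self) -> bool:
        return self.primary_drying_end_min is not None

    def mass_sublimed_g(self) -> float:
        return self.initial_ice_mass_g - float(self.frame.ice_mass_g.iloc[-1])


def primary_drying_time(trace: DryingTrace) -> float | str:
    """Primary-drying duration in hours, or ``"incomplete"`` if ice remains."""
    if trace.primary_drying_end_min is None:
        return "incomplete"
    return trace.primary_drying_end_min / 60.0


def collapse_risk(tp_c: float, tg_prime_c: float) -> bool:
    """True iff the product temperature exceeds Tg' (micro-collapse risk)."""
    return tp_c > tg_prime_c


def simulate_primary_drying(
    geometry: VialGeometry,
    formulation: Formulation,
    heat_params: HeatTransferParams,
    mass_params: MassTransferParams,
    schedule: "schedules.MicrowaveCycle | schedules.LyoCycle",
    mode: str,
    mvd_power: MvdPowerParams | None = None,
    position_modifier: PositionModifier | None = None,
    dt_min: float = 0.5,
    t_stop_min: float | None = None,
    corr: IceCorrelation = DEFAULT_ICE,
) -> DryingTrace:
    """Run the quasi-steady primary-drying simulation under a schedule.

    The trace ends when the ice is exhausted (the final partial step is cut
    exactly at exhaustion), when the schedule ends, or at ``t_stop_min``.
    Mass is conserved to machine precision: sublimed + remaining = initial.
    Chamber pressure is taken as the midpoint of each step's vacuum band
    (lyo: the step's setpoint).
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    if mode not in ("mvd", "lyo"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mvd" and not isinstance(schedule, schedules.MicrowaveCycle):
        raise TypeError("mvd mode requires a MicrowaveCycle")
    if mode == "lyo" and not isinstance(schedule, schedules.LyoCycle):
        raise TypeError("lyo mode requires a LyoCycle")
    if mode == "mvd" and mvd_power is None:
        mvd_power = MvdPowerParams()
    modifier = position_modifier or PositionModifier()

    ice0 = formulation.water_mass_g(geometry.fill_volume_ml)
    if ice0 <= 0:
        raise ValueError("initial ice mass must be positive")
    fill_height_m = geometry.fill_height_m

    t_end = schedule.total_duration_min
    if t_stop_min is not None:
        t_end = min(t_end, t_stop_min)

    rows = []
    ice = ice0
    tp = celsius_to_kelvin(-40.0)   # placeholder until first solve
    heat_J = 0.0
    end_min: float | None = None
    t = 0.0

    def record(time_min: float) -> None:
        frac = 1.0 - ice / ice0
        rows.append((time_min, ice, fill_height_m * frac, tp, frac))

    while t < t_end - 1e-12 and ice > 0:
        step_dt = min(dt_min, t_end - t)
        if mode == "mvd":
            applied = schedules.power_at(schedule, t)
            self_mod = (ice / ice0) ** mvd_power.self_regulation_gamma
            mw_w = (applied * mvd_power.absorption_efficiency * self_mod
                    / mvd_power.n_vials_in_chamber)
            hp = heat_params
            step = schedule.steps[_step_index(schedule, t)]
            pc_torr = 0.5 * (step.vacuum_lo_mtorr + step.vacuum_hi_mtorr) / 1000.0
        else:
            ts_K = celsius_to_kelvin(schedules.shelf_temperature_at(schedule, t))
            hp = with_shelf_temperature(heat_params, ts_K)
            mw_w = 0.0
            step = schedule.steps[_lyo_step_index(schedule, t)]
            pc_torr = step.vacuum_mtorr / 1000.0

        dried_layer_cm = fill_height_m * 100.0 * (1.0 - ice / ice0)
        try:
            tp, rate_gph = solve_steady_state(
                geometry, hp, mass_params, pc_torr,
                dried_layer_cm=dried_layer_cm, microwave_w=mw_w,
                heat_scale=modifier.kv_multiplier, corr=corr)
        except RuntimeError as exc:
            raise RuntimeError(
                f"steady state failed at t = {t:.2f} min "
                f"(ice = {ice:.4f} g, fraction = {1 - ice / ice0:.4f}): {exc}"
            ) from exc
        if len(rows) == 0:
            record(0.0)
        rate_gph = max(rate_gph, 0.0)   # condensation clamp: ice cannot grow the trace
        dm = rate_gph * step_dt / 60.0
        if dm >= ice and rate_gph > 0:
            # exhaust exactly within this step
            partial = ice / (rate_gph / 60.0)
            heat_J += CONSTANTS.enthalpy_sublimation_J_per_g * ice
            t += partial
            ice = 0.0
            end_min = t
            record(t)
            break
        heat_J += CONSTANTS.enthalpy_sublimation_J_per_g * dm
        ice -= dm
        t += step_dt
        record(t)

    if not rows:   # zero-duration or immediate exhaustion edge case
        record(0.0)
    frame = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    return DryingTrace(frame=frame, mode=mode, schedule_name=schedule.name,
                       location_class=modifier.location_class,
                       initial_ice_mass_g=ice0,
                       primary_drying_end_min=end_min, heat_input_J=heat_J)


def _step_index(cycle: "schedules.MicrowaveCycle", t_min: float) -> int:
    import bisect
    ends = cycle.step_ends_min
    if t_min >= ends[-1]:
        return len(ends) - 1
    return bisect.bisect_right(ends, t_min)


def _lyo_step_index(cycle: "schedules.LyoCycle", t_min: float) -> int:
    # attribute t to the step whose ramp+hold window contains it
    t = 0.0
    temp = cycle.steps[0].setpoint_c
    for i, step in enumerate(cycle.steps):
        ramp = 0.0
        if step.ramp_c_per_min > 0 and step.setpoint_c != temp:
            ramp = abs(step.setpoint_c - temp) / step.ramp_c_per_min
        t += ramp + step.hold_min
        temp = step.setpoint_c
        if t_min < t:
            return i
    return len(cycle.steps) - 1


def simulate_vial_population(
    geometry: VialGeometry,
    formulation: Formulation,
    heat_params: HeatTransferParams,
    mass_params: MassTransferParams,
    schedule: "schedules.MicrowaveCycle | schedules.LyoCycle",
    mode: str,
    layout_classes: Mapping[str, int],
    modifiers: Mapping[str, PositionModifier] | None = None,
    t_stop_min: float | None = None,
    mvd_power: MvdPowerParams | None = None,
    dt_min: float = 0.5,
) -> pd.DataFrame:
    """Per-vial fraction sublimed at ``t_stop`` for a classed layout.

    ``layout_classes`` maps location class -> number of vials.  One trace is
    run per class and its terminal fraction assigned to every vial of that
    class (the simulator is deterministic, so per-vial repetition would be
    redundant).  Returns a frame with columns (vial_index, location_class,
    fraction_sublimed).
    """
    if modifiers is None:
        modifiers = DEFAULT_MVD_MODIFIERS if mode == "mvd" else DEFAULT_LYO_MODIFIERS
    missing = set(layout_classes) - set(modifiers)
    if missing:
        raise ValueError(f"no position modifier for classes: {sorted(missing)}")
    records = []
    idx = 0
    for cls, n in layout_classes.items():
        trace = simulate_primary_drying(
            geometry, formulation, heat_params, mass_params, schedule, mode,
            mvd_power=mvd_power, position_modifier=modifiers[cls],
            dt_min=dt_min, t_stop_min=t_stop_min)
        frac = float(trace.frame.fraction_sublimed.iloc[-1])
        for _ in range(n):
            records.append((idx, cls, frac))
            idx += 1
    return pd.DataFrame(records, columns=["vial_index", "location_class",
                                          "fraction_sublimed"])
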