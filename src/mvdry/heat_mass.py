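"""Steady-state heat and mass transfer model of primary drying.

The model couples two classical relations.  Mass transfer: the sublimation
rate through the dried cake is

    dm/dt = Ap (Pi - Pc) / Rp

with Ap the product cross-section, Pi the ice-interface vapor pressure
(a function of product temperature through the ice correlation), Pc the
chamber pressure and Rp the product resistance.  Heat transfer: the heat
reaching the sublimation front is the sum of shelf conduction lumped into a
vial heat transfer coefficient Kv = Kc + Kr + Kg, top radiation from the
lid/upper shelf, and — for microwave vacuum drying — a volumetric
dielectric-heating term.  At steady state the heat supplied balances the
latent-heat demand

    Q_total(Tp) = dHs * dm/dt(Tp)

which pins down the product temperature Tp and hence the rate.  The solver
finds Tp by bracketed root finding on [180, 273] K; the balance residual is
strictly decreasing in Tp (heat supply falls, latent demand rises), so the
root is unique whenever it exists.

Unit conventions: areas for heat transfer in m^2 and temperatures in K;
the sublimation law is evaluated in the lyophilization literature's
customary Torr * h * cm^2 / g resistance system, so product areas enter it
in cm^2 and rates come out in g/h.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from scipy.optimize import brentq

from .thermo import CONSTANTS, DEFAULT_ICE, IceCorrelation, ice_vapor_pressure

SECONDS_PER_HOUR = 3600.0


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class VialGeometry:
    """Vial and fill geometry.

    ``outer_area_m2`` (Av) is the vial's outer cross-section, which receives
    shelf heat; ``product_area_m2`` (Ap) is the inner cake cross-section
    through which vapor escapes.  ``fill_height_m`` must be consistent with
    fill volume over product area.
    """

    outer_area_m2: float = 2.27e-4       # 17 mm OD ISO 2R vial
    product_area_m2: float = 1.767e-4    # ~15 mm inner diameter
    fill_volume_ml: float = 0.7
    inner_diameter_m: float = 0.015

    def __post_init__(self) -> None:
        if not 0 < self.product_area_m2 <= self.outer_area_m2:
            raise ValueError("require 0 < product_area_m2 <= outer_area_m2")
        if self.fill_volume_ml <= 0:
            raise ValueError("fill_volume_ml must be positive")

    @property
    def fill_height_m(self) -> float:
        return self.fill_volume_ml * 1e-6 / self.product_area_m2

    @property
    def product_area_cm2(self) -> float:
        return self.product_area_m2 * 1e4


@dataclass(frozen=True)
class HeatTransferParams:
    """Conventional (non-microwave) heat-transfer parameters.

    Kv is decomposed as Kc (contact conduction) + Kr (shelf radiation,
    ``shelf_radiation_coeff * shelf_emissivity``) + Kg (gas conduction).
    The shelf-radiation coefficient defaults to 4.6 W m^-2 K^-1 per unit
    emissivity (the classical 1.1e-4 cal s^-1 cm^-2 K^-1 literature value
    in SI); it is configurable because the literature states it in mixed
    unit systems.  ``kg_of_pressure`` optionally makes Kg a function of
    chamber pressure (Torr); by default Kg is pressure-independent.
    """

    Kc: float = 1.6
    Kg: float = 1.0
    shelf_emissivity: float = 0.18
    vial_top_emissivity: float = 0.84
    shelf_temperature_K: float = 258.15
    lid_temperature_K: float = 258.15
    shelf_radiation_coeff: float = 4.6
    kg_of_pressure: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        for name in ("Kc", "Kg", "shelf_radiation_coeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("shelf_emissivity", "vial_top_emissivity"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def kv(self, chamber_pressure_torr: float | None = None) -> float:
        kg = self.Kg
        if self.kg_of_pressure is not None and chamber_pressure_torr is not None:
            kg = self.kg_of_pressure(chamber_pressure_torr)
        return combine_kv(self.Kc, self.shelf_radiation_coeff * self.shelf_emissivity, kg)


@dataclass(frozen=True)
class MassTransferParams:
    """Dried-cake resistance model Rp(l) = R0 + A1 l / (1 + A2 l).

    Units are the customary Torr h cm^2 / g system, with the dried-layer
    thickness l in cm.  A1 = 0 recovers the constant (lumped) resistance
    used in first-order design-space comparisons.
    """

    R0: float = 1.4
    A1: float = 16.0
    A2: float = 0.0

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("A1 and A2 must be non-negative")


@dataclass(frozen=True)
class DielectricProperties:
    """Material response to the microwave field.

    Either the physical route (dielectric constant, loss tangent and the
    lumped proportionality constant of the volumetric dissipation law) or
    the empirical route (``absorption_efficiency``, the fitted fraction of
    applied power absorbed, as measured by the absorption pipeline) can be
    used; the simulator's default pathway is the empirical one.
    """

    dielectric_constant: float = 78.0
    loss_tangent: float = 0.1
    lumped_constant: float = 0.0   # units chosen so Pd is W/m^3; equipment-specific input
    absorption_efficiency: float = 0.12

    def __post_init__(self) -> None:
        if self.dielectric_constant < 1:
            raise ValueError("dielectric_constant must be >= 1")
        if self.loss_tangent < 0:
            raise ValueError("loss_tangent must be non-negative")
        if not 0 <= self.absorption_efficiency <= 1:
            raise ValueError("absorption_efficiency must lie in [0, 1]")


@dataclass(frozen=True)
class MicrowaveField:
    """Nominal microwave excitation and chamber loading."""

    frequency_hz: float = 2.45e9
    field_strength_v_per_m: float = 0.0
    applied_power_w: float = 0.0
    n_vials_in_chamber: int = 224

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.applied_power_w < 0:
            raise ValueError("applied_power_w must be non-negative")
        if self.n_vials_in_chamber < 1:
            raise ValueError("n_vials_in_chamber must be >= 1")


# ---------------------------------------------------------------------------
# elementary operations


def sublimation_rate(area_cm2: float, pi_torr: float, pc_torr: float, rp: float) -> float:
    """Sublimation rate Ap (Pi - Pc) / Rp in g/h.

    ``area_cm2`` is the product cross-section in cm^2 and ``rp`` the cake
    resistance in Torr h cm^2 / g.  A negative result (chamber above the
    interface pressure) means condensation; it is returned as-is so callers
    can flag it.
    """
    if area_cm2 <= 0:
        raise ValueError("product area must be positive")
    if rp <= 0:
        raise ValueError("mass transfer resistance must be positive")
    return area_cm2 * (pi_torr - pc_torr) / rp


def driving_force_increase(pi_a: float, pc_a: float, pi_b: float, pc_b: float) -> float:
    """Percent increase of driving force (Pi_a - Pc_a) over (Pi_b - Pc_b)."""
    ref = pi_b - pc_b
    if ref <= 0:
        raise ValueError("reference driving force must be positive")
    return 100.0 * ((pi_a - pc_a) - ref) / ref


def dried_layer_resistance(thickness_cm: float, params: MassTransferParams) -> float:
    """Cake resistance at dried-layer thickness l (cm), Torr h cm^2 / g."""
    if thickness_cm < 0:
        raise ValueError("dried-layer thickness must be non-negative")
    return params.R0 + params.A1 * thickness_cm / (1.0 + params.A2 * thickness_cm)


def conductive_heat_flux(kv: float, av_m2: float, ts_K: float, tb_K: float) -> float:
    """Lumped shelf-to-product heat flow Kv Av (Ts - Tb), W."""
    if kv < 0:
        raise ValueError("Kv must be non-negative")
    if av_m2 <= 0:
        raise ValueError("vial area must be positive")
    return kv * av_m2 * (ts_K - tb_K)


def combine_kv(kc: float, kr: float, kg: float) -> float:
    """Kv = Kc + Kr + Kg."""
    if min(kc, kr, kg) < 0:
        raise ValueError("Kv components must be non-negative")
    return kc + kr + kg


def radiative_flux(av_m2: float, ev: float, ti_K: float, t_K: float,
                   sigma: float = CONSTANTS.stefan_boltzmann) -> float:
    """Top radiation Av ev sigma (Ti^4 - T^4), W."""
    if not 0 <= ev <= 1:
        raise ValueError("emissivity must lie in [0, 1]")
    return av_m2 * ev * sigma * (ti_K ** 4 - t_K ** 4)


def microwave_power_dissipated(k: float, epsilon: float, tan_delta: float,
                               frequency_hz: float, field_v_per_m: float) -> float:
    """Volumetric dielectric heating Pd = K eps tan(delta) f E^2, W/m^3."""
    if epsilon < 1:
        raise ValueError("dielectric constant must be >= 1")
    if min(k, tan_delta, frequency_hz, field_v_per_m) < 0:
        raise ValueError("inputs must be non-negative")
    return k * epsilon * tan_delta * frequency_hz * field_v_per_m ** 2


def absorbed_microwave_per_vial(applied_power_w: float, efficiency: float,
                                n_vials: int, self_mod: float = 1.0) -> float:
    """Per-vial absorbed microwave power, W.

    ``efficiency`` is the fitted fraction of applied power absorbed by the
    load; ``self_mod`` in [0, 1] implements the self-regulation hypothesis
    (absorption falls as residual moisture falls).
    """
    if n_vials < 1:
        raise ValueError("n_vials must be >= 1")
    if not 0 <= efficiency <= 1:
        raise ValueError("efficiency must lie in [0, 1]")
    if not 0 <= self_mod <= 1:
        raise ValueError("self_mod must lie in [0, 1]")
    return applied_power_w * efficiency * self_mod / n_vials


def total_heat_flux(conduction_w: float, convection_w: float,
                    radiation_w: float, microwave_w: float) -> float:
    """Total heat to the sublimation front: the conventional terms plus microwave."""
    return conduction_w + convection_w + radiation_w + microwave_w


# ---------------------------------------------------------------------------
# steady-state solver

_BRACKET_K = (180.0, 273.0)


def energy_balance_residual(tp_K: float, geometry: VialGeometry,
                            heat_params: HeatTransferParams,
                            rp: float, pc_torr: float,
                            microwave_w: float = 0.0,
                            heat_scale: float = 1.0,
                            corr: IceCorrelation = DEFAULT_ICE) -> float:
    """Heat supplied minus latent-heat demand at product temperature Tp, W.

    ``heat_scale`` multiplies the non-microwave heat input only; it is how
    position-dependent (edge-vial) excess heat is modelled.
    """
    q_cond = conductive_heat_flux(heat_params.kv(pc_torr), geometry.outer_area_m2,
                                  heat_params.shelf_temperature_K, tp_K)
    q_rad = radiative_flux(geometry.outer_area_m2, heat_params.vial_top_emissivity,
                           heat_params.lid_temperature_K, tp_K)
    q_in = total_heat_flux(heat_scale * q_cond, 0.0, heat_scale * q_rad, microwave_w)
    rate = sublimation_rate(geometry.product_area_cm2, ice_vapor_pressure(tp_K, corr),
                            pc_torr, rp)
    q_demand = CONSTANTS.enthalpy_sublimation_J_per_g * rate / SECONDS_PER_HOUR
    return q_in - q_demand


def solve_steady_state(geometry: VialGeometry, heat_params: HeatTransferParams,
                       mass_params: MassTransferParams, pc_torr: float,
                       dried_layer_cm: float = 0.0, microwave_w: float = 0.0,
                       heat_scale: float = 1.0,
                       corr: IceCorrelation = DEFAULT_ICE) -> tuple[float, float]:
    """Solve the primary-drying energy balance for (Tp [K], rate [g/h]).

    Finds the product temperature at which the total heat flux equals the
    latent-heat demand of sublimation, by Brent root-finding on a fixed
    [180, 273] K bracket, then polishes by bisection until the residual is
    below 1e-9 W.  Deterministic; raises if the balance has no root in the
    bracket (too little or too much heat), reporting both endpoint
    residuals.
    """
    rp = dried_layer_resistance(dried_layer_cm, mass_params)

    def residual(t: float) -> float:
        return energy_balance_residual(t, geometry, heat_params, rp, pc_torr,
                                       microwave_w, heat_scale, corr)

    lo, hi = _BRACKET_K
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        tp = lo
    elif r_hi == 0.0:
        tp = hi
    elif r_lo * r_hi > 0:
        raise RuntimeError(
            "steady-state energy balance has no root in "
            f"[{lo}, {hi}] K: residual({lo}) = {r_lo:.3e} W, "
            f"residual({hi}) = {r_hi:.3e} W"
        )
    else:
        tp = brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)
        # polish: bisect the bracket down until the residual meets 1e-9 W
        a, b = max(lo, tp - 1e-6), min(hi, tp + 1e-6)
        ra, rb = residual(a), residual(b)
        if ra * rb <= 0:
            for _ in range(200):
                if abs(residual(tp)) < 1e-9:
                    break
                mid = 0.5 * (a + b)
                if residual(a) * residual(mid) <= 0:
                    b = mid
                else:
                    a = mid
                tp = 0.5 * (a + b)
    rate = sublimation_rate(geometry.product_area_cm2,
                            ice_vapor_pressure(tp, corr), pc_torr, rp)
    return tp, rate


def with_shelf_temperature(heat_params: HeatTransferParams, ts_K: float,
                           lid_follows_shelf: bool = True) -> HeatTransferParams:
    """Copy of ``heat_params`` with a new shelf (and optionally lid) temperature."""
    lid = ts_K if lid_follows_shelf else heat_params.lid_temperature_K
    return replace(heat_params, shelf_temperature_K=ts_K, lid_temperature_K=lid)
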