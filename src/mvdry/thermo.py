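"""Thermodynamic backbone for primary-drying calculations.

Everything downstream — sublimation driving forces, steady-state energy
balances, gravimetric-to-power conversions — rests on three things housed
here: a small set of physical constants, exact pressure-unit conversions
(Pa / Torr / mTorr), and the saturation vapor pressure of ice as a function
of temperature.

The ice vapor-pressure curve is represented by a single-term
Clausius–Clapeyron correlation

    P_ice(T) = A * exp(-B / T)        [P in Torr, T in K]

with default A = 2.698e10 Torr and B = 6144.96 K.  Over the primary-drying
window (roughly -90 to 0 degC) this form tracks the sublimation line of ice
to well under a percent, and with the default parameters it reproduces the
two benchmark interface pressures used throughout this package: 187 mTorr
at -34 degC and 135 mTorr at -37 degC (nearest-mTorr rounding).  The
correlation is a replaceable object, so an alternative formulation (e.g.
Wagner-type) can be swapped in without touching any consumer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and exact unit-conversion factors.

    Attributes
    ----------
    enthalpy_sublimation_J_per_g:
        Latent heat of sublimation of ice, J/g.  Treated as constant
        (2840 J/g) over the primary-drying temperature range.
    stefan_boltzmann:
        sigma, W m^-2 K^-4.
    speed_of_light:
        c, m/s (exact).
    torr_per_pascal:
        1 Pa = 7.50062e-3 Torr.
    mtorr_per_torr:
        1 Torr = 1000 mTorr (exact).
    """

    enthalpy_sublimation_J_per_g: float = 2840.0
    stefan_boltzmann: float = 5.670374419e-8
    speed_of_light: float = 299_792_458.0
    torr_per_pascal: float = 7.50062e-3
    mtorr_per_torr: float = 1000.0

    def __post_init__(self) -> None:
        if self.enthalpy_sublimation_J_per_g <= 0:
            raise ValueError("enthalpy_sublimation_J_per_g must be positive")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class IceCorrelation:
    """Clausius–Clapeyron correlation for the vapor pressure of ice.

    P(T) = prefactor_torr * exp(-activation_K / T), valid on
    ``valid_range_K`` (default 180–273.16 K, i.e. deep freeze up to the
    triple point).
    """

    prefactor_torr: float = 2.698e10
    activation_K: float = 6144.96
    valid_range_K: tuple[float, float] = (180.0, 273.16)

    def __post_init__(self) -> None:
        if self.prefactor_torr <= 0:
            raise ValueError("prefactor_torr must be positive")
        if self.activation_K <= 0:
            raise ValueError("activation_K must be positive")
        lo, hi = self.valid_range_K
        if not lo < hi:
            raise ValueError("valid_range_K must be an increasing interval")


DEFAULT_ICE = IceCorrelation()

#: Unit -> Torr multiplier for the pressure units this package understands.
_PRESSURE_UNITS_TO_TORR = {
    "Pa": CONSTANTS.torr_per_pascal,
    "Torr": 1.0,
    "mTorr": 1.0 / CONSTANTS.mtorr_per_torr,
}


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15


def ice_vapor_pressure(temperature_K: float, corr: IceCorrelation = DEFAULT_ICE) -> float:
    """Saturation vapor pressure of ice, in Torr.

    Parameters
    ----------
    temperature_K:
        Ice-interface temperature in kelvin; must lie inside
        ``corr.valid_range_K``.
    corr:
        The vapor-pressure correlation to evaluate.

    Raises
    ------
    ValueError
        If the temperature is outside the correlation's valid range.
    """
    lo, hi = corr.valid_range_K
    if not lo <= temperature_K <= hi:
        raise ValueError(
            f"temperature {temperature_K} K outside correlation valid range "
            f"[{lo}, {hi}] K"
        )
    return corr.prefactor_torr * math.exp(-corr.activation_K / temperature_K)


def invert_ice_vapor_pressure(pressure_torr: float, corr: IceCorrelation = DEFAULT_ICE) -> float:
    """Temperature (K) at which ice has the given vapor pressure (Torr).

    Closed-form inverse of :func:`ice_vapor_pressure`:
    T = B / ln(A / P).  The pressure must be positive and within the image
    of the correlation's valid temperature range.
    """
    if pressure_torr <= 0:
        raise ValueError("pressure must be positive")
    lo, hi = corr.valid_range_K
    p_lo = corr.prefactor_torr * math.exp(-corr.activation_K / lo)
    p_hi = corr.prefactor_torr * math.exp(-corr.activation_K / hi)
    if not p_lo <= pressure_torr <= p_hi:
        raise ValueError(
            f"pressure {pressure_torr} Torr outside image of valid range "
            f"[{p_lo:.3e}, {p_hi:.3e}] Torr"
        )
    return corr.activation_K / math.log(corr.prefactor_torr / pressure_torr)


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Exact linear conversion among Pa, Torr and mTorr."""
    try:
        to_torr = _PRESSURE_UNITS_TO_TORR[from_unit]
        from_torr = _PRESSURE_UNITS_TO_TORR[to_unit]
    except KeyError as exc:
        supported = ", ".join(sorted(_PRESSURE_UNITS_TO_TORR))
        raise ValueError(f"unknown pressure unit {exc.args[0]!r}; supported: {supported}") from None
    return value * to_torr / from_torr


def pressure_mtorr(temperature_K: float, corr: IceCorrelation = DEFAULT_ICE) -> float:
    """Convenience: ice vapor pressure in mTorr (as reported in cycle logs)."""
    return convert_pressure(ice_vapor_pressure(temperature_K, corr), "Torr", "mTorr")


def free_space_wavelength(frequency_hz: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Free-space wavelength c/f in metres.

    At the 2.45 GHz ISM band used by microwave vacuum dryers this is
    12.2 cm, which sets the scale of the penetration depth of the field
    into the product.
    """
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return constants.speed_of_light / frequency_hz
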