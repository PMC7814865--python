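"""Microwave-absorption efficiency analysis from gravimetric water loss.

Constant-power microwave runs remove water from frozen sucrose solutions;
the mass lost per vial per hour, multiplied by the enthalpy of sublimation
(2840 J/g), gives the power actually absorbed.  Zero-power background runs
capture radiative and other extraneous heat leaks, which are subtracted
per concentration stratum.  Absorbed power is normalized by the vial
surface area and applied power by the dryer shelf area (the two reference
areas are equipment inputs, not universal constants), and an ordinary
least-squares line of absorbed vs applied power is fitted per sucrose
concentration.  Its slope is the *absorption efficiency* — an empirical
stand-in for the dielectric constant / loss tangent product — and a second
OLS fit of efficiency against sucrose concentration quantifies how solute
content improves microwave coupling.

Because the two normalizations use different areas, the normalized slope
carries a factor (shelf area / vial area); the raw power-ratio slope
(absorbed W per applied W) is reported alongside for interpretability.

Run records are delimited text with columns
``sucrose_pct_wv, applied_power_W, duration_h, n_vials, mass_removed_g_per_vial``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .thermo import CONSTANTS

RUN_COLUMNS = ["sucrose_pct_wv", "applied_power_W", "duration_h",
               "n_vials", "mass_removed_g_per_vial"]

#: Documented placeholder reference areas (m^2); the true values are
#: equipment-specific and should be supplied in the study config.
DEFAULT_SHELF_AREA_M2 = 0.20      # rotating circular shelf of a lab-scale dryer
DEFAULT_VIAL_AREA_M2 = 2.3e-3     # external surface of a 3-cc vial


@dataclass(frozen=True)
class AbsorptionRun:
    """One constant-power drying run (mean over its vials)."""

    sucrose_pct_wv: float
    applied_power_w: float
    duration_h: float
    n_vials: int
    mass_removed_g_per_vial: float

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.mass_removed_g_per_vial < 0:
            raise ValueError("mass removed must be non-negative")
        if self.applied_power_w < 0:
            raise ValueError("applied power must be non-negative")

    @property
    def is_background(self) -> bool:
        return self.applied_power_w == 0


@dataclass(frozen=True)
class EfficiencyFit:
    """OLS fit of absorbed vs applied power for one concentration."""

    sucrose_pct_wv: float
    slope: float                  # normalized-efficiency slope (area ratio folded in)
    intercept_w_per_m2: float
    r_squared: float
    n_points: int
    raw_power_ratio_slope: float  # absorbed W per applied W, unnormalized

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a fit needs at least 2 points")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")


def absorbed_power(mass_removed_g: float, duration_h: float,
                   dhs_J_per_g: float = CONSTANTS.enthalpy_sublimation_J_per_g) -> float:
    """Convert gravimetric water loss to absorbed power, W."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    return dhs_J_per_g * mass_removed_g / (duration_h * 3600.0)


def mass_from_power(power_w: float, duration_h: float,
                    dhs_J_per_g: float = CONSTANTS.enthalpy_sublimation_J_per_g) -> float:
    """Inverse of :func:`absorbed_power`: mass (g) sublimed by a power over a duration."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    return power_w * duration_h * 3600.0 / dhs_J_per_g


def subtract_background(runs: list[AbsorptionRun],
                        dhs_J_per_g: float = CONSTANTS.enthalpy_sublimation_J_per_g,
                        ) -> pd.DataFrame:
    """Background-corrected absorbed power per non-background run.

    Each concentration stratum must contain exactly one zero-power
    background run; its absorbed power (radiation and other extraneous
    heat) is subtracted from every powered run of that stratum.  Returns a
    frame (sucrose_pct_wv, applied_power_W, absorbed_W) without the
    background rows.
    """
    by_conc: dict[float, list[AbsorptionRun]] = {}
    for run in runs:
        by_conc.setdefault(run.sucrose_pct_wv, []).append(run)
    rows = []
    for conc, group in sorted(by_conc.items()):
        backgrounds = [r for r in group if r.is_background]
        if len(backgrounds) != 1:
            raise ValueError(
                f"concentration stratum {conc}% w/v needs exactly one "
                f"background (0 W) run, found {len(backgrounds)}")
        bg_power = absorbed_power(backgrounds[0].mass_removed_g_per_vial,
                                  backgrounds[0].duration_h, dhs_J_per_g)
        for run in group:
            if run.is_background:
                continue
            corrected = absorbed_power(run.mass_removed_g_per_vial,
                                       run.duration_h, dhs_J_per_g) - bg_power
            rows.append((conc, run.applied_power_w, corrected))
    return pd.DataFrame(rows, columns=["sucrose_pct_wv", "applied_power_W",
                                       "absorbed_W"])


def normalize_by_area(power_w: float, area_m2: float) -> float:
    """Power per unit area, W/m^2."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return power_w / area_m2


def fit_absorption_line(applied: np.ndarray, absorbed: np.ndarray,
                        sucrose_pct_wv: float = float("nan"),
                        raw_slope: float | None = None) -> EfficiencyFit:
    """OLS of absorbed vs applied (both W/m^2) with a free intercept.

    The free intercept absorbs residual heat leaks that the background
    subtraction did not capture.  Raises if fewer than two distinct applied
    values are given (the slope is then unidentifiable).
    """
    applied = np.asarray(applied, dtype=float)
    absorbed = np.asarray(absorbed, dtype=float)
    if applied.size < 2 or np.unique(applied).size < 2:
        raise ValueError("need >= 2 distinct applied-power values to fit a line")
    res = linregress(applied, absorbed)
    return EfficiencyFit(sucrose_pct_wv=sucrose_pct_wv, slope=float(res.slope),
                         intercept_w_per_m2=float(res.intercept),
                         r_squared=float(res.rvalue ** 2), n_points=applied.size,
                         raw_power_ratio_slope=(float(res.slope) if raw_slope is None
                                                else raw_slope))


def efficiency_vs_concentration(concentrations: np.ndarray, slopes: np.ndarray):
    """OLS of absorption efficiency on sucrose concentration (% w/v).

    Returns (gradient per % w/v, intercept, r_squared).
    """
    concentrations = np.asarray(concentrations, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if np.unique(concentrations).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    res = linregress(concentrations, slopes)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def analyze_absorption_study(runs: list[AbsorptionRun],
                             shelf_area_m2: float = DEFAULT_SHELF_AREA_M2,
                             vial_area_m2: float = DEFAULT_VIAL_AREA_M2,
                             dhs_J_per_g: float = CONSTANTS.enthalpy_sublimation_J_per_g,
                             ) -> tuple[list[EfficiencyFit], tuple[float, float, float]]:
    """Full absorption analysis: background-correct, normalize, fit, regress.

    Returns the per-concentration fits (absorbed W/m^2 vial area vs applied
    W/m^2 shelf area) and the (gradient, intercept, r^2) of the raw
    power-ratio efficiency against concentration.
    """
    corrected = subtract_background(runs, dhs_J_per_g)
    fits = []
    for conc, grp in corrected.groupby("sucrose_pct_wv"):
        applied_norm = grp["applied_power_W"].to_numpy() / shelf_area_m2
        absorbed_norm = grp["absorbed_W"].to_numpy() / vial_area_m2
        raw = linregress(grp["applied_power_W"], grp["absorbed_W"])
        fits.append(fit_absorption_line(applied_norm, absorbed_norm,
                                        sucrose_pct_wv=float(conc),
                                        raw_slope=float(raw.slope)))
    concs = np.array([f.sucrose_pct_wv for f in fits])
    raw_slopes = np.array([f.raw_power_ratio_slope for f in fits])
    conc_fit = efficiency_vs_concentration(concs, raw_slopes)
    return fits, conc_fit


def read_absorption_runs(path: str | Path) -> list[AbsorptionRun]:
    """Read absorption-study runs from delimited text, validating the schema."""
    df = pd.read_csv(path)
    missing = set(RUN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"runs file {path} missing columns: {sorted(missing)}")
    return [AbsorptionRun(r.sucrose_pct_wv, r.applied_power_W, r.duration_h,
                          int(r.n_vials), r.mass_removed_g_per_vial)
            for r in df.itertuples()]
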