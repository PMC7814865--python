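"""Drying-cycle schedules: microwave power steps and shelf-temperature ramps.

A microwave cycle is an ordered list of constant-power exposure steps
(duration, number of magnetrons, power per magnetron, vacuum band); a
lyophilizer cycle is an ordered list of shelf-temperature setpoints with
ramp rates and holds.  This module evaluates power or shelf temperature at
any time, integrates energy exposure exactly (the power profile is
piecewise constant), and handles the fractional-cycle-time normalization
used to compare partial drying runs across the two technologies.

Step intervals are half-open [start, end): a time exactly on a boundary
belongs to the later step.

The benchmark cycles used throughout the package ship as delimited-text
fixtures under ``mvdry/data/schedules`` and are loadable by name via
:func:`load_builtin_cycle` (microwave: ``mvd_full``, ``mvd_visualization``,
``mvd_protein``, ``mvd_terminal_temp``, ``mvd_ssa``; lyophilizer:
``lyo_benchmark``, ``lyo_protein``).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

MVD_SCHEDULE_COLUMNS = ["duration_min", "n_magnetrons", "power_per_magnetron_W",
                        "vacuum_lo_mTorr", "vacuum_hi_mTorr"]
LYO_SCHEDULE_COLUMNS = ["setpoint_C", "ramp_C_per_min", "hold_min", "vacuum_mTorr"]


@dataclass(frozen=True)
class PowerStep:
    """One constant-power microwave exposure step."""

    duration_min: float
    n_magnetrons: int
    power_per_magnetron_w: float
    vacuum_lo_mtorr: float = 50.0
    vacuum_hi_mtorr: float = 80.0

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        if self.n_magnetrons < 0 or self.power_per_magnetron_w < 0:
            raise ValueError("magnetron count and power must be non-negative")

    @property
    def total_power_w(self) -> float:
        return self.n_magnetrons * self.power_per_magnetron_w


@dataclass(frozen=True)
class MicrowaveCycle:
    """Ordered microwave power steps."""

    steps: tuple[PowerStep, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a cycle needs at least one step")

    @property
    def total_duration_min(self) -> float:
        return sum(s.duration_min for s in self.steps)

    @property
    def step_ends_min(self) -> list[float]:
        ends, t = [], 0.0
        for s in self.steps:
            t += s.duration_min
            ends.append(t)
        return ends


@dataclass(frozen=True)
class LyoStep:
    """One shelf-temperature segment: ramp to setpoint, then hold."""

    setpoint_c: float
    ramp_c_per_min: float
    hold_min: float
    vacuum_mtorr: float = 40.0

    def __post_init__(self) -> None:
        if self.hold_min < 0:
            raise ValueError("hold_min must be non-negative")
        if self.ramp_c_per_min < 0:
            raise ValueError("ramp_c_per_min must be non-negative")


@dataclass(frozen=True)
class LyoCycle:
    """Ordered shelf-temperature steps; profile is piecewise linear."""

    steps: tuple[LyoStep, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a cycle needs at least one step")

    def _segments(self) -> list[tuple[float, float, float, float]]:
        """(t_start, t_end, T_start, T_end) segments, ramps and holds alternating."""
        segs = []
        t = 0.0
        temp = self.steps[0].setpoint_c   # profile starts at the first setpoint
        for step in self.steps:
            if step.ramp_c_per_min > 0 and step.setpoint_c != temp:
                ramp_time = abs(step.setpoint_c - temp) / step.ramp_c_per_min
                segs.append((t, t + ramp_time, temp, step.setpoint_c))
                t += ramp_time
            temp = step.setpoint_c
            if step.hold_min > 0:
                segs.append((t, t + step.hold_min, temp, temp))
                t += step.hold_min
        return segs

    @property
    def total_duration_min(self) -> float:
        segs = self._segments()
        return segs[-1][1] if segs else 0.0


def power_at(cycle: MicrowaveCycle, t_min: float) -> float:
    """Total power (W) of the step containing time t; [start, end) intervals."""
    if t_min < 0 or t_min > cycle.total_duration_min:
        raise ValueError(
            f"t = {t_min} min outside cycle [0, {cycle.total_duration_min}] min")
    ends = cycle.step_ends_min
    if t_min == cycle.total_duration_min:   # convention: cycle end reports last step
        return cycle.steps[-1].total_power_w
    idx = bisect.bisect_right(ends, t_min)
    return cycle.steps[idx].total_power_w


def total_energy_exposure(cycle: MicrowaveCycle, t_end_min: float | None = None) -> float:
    """Exact integral of power over [0, t_end], in kWh.

    The profile is piecewise constant, so the integral is a step-wise sum
    with a pro-rated final step.  ``t_end`` defaults to the full cycle.
    """
    if t_end_min is None:
        t_end_min = cycle.total_duration_min
    if t_end_min < 0:
        raise ValueError("t_end must be non-negative")
    if t_end_min > cycle.total_duration_min:
        raise ValueError(
            f"t_end = {t_end_min} min beyond cycle end {cycle.total_duration_min} min")
    energy_w_min = 0.0
    start = 0.0
    for step in cycle.steps:
        end = start + step.duration_min
        overlap = max(0.0, min(end, t_end_min) - start)
        energy_w_min += step.total_power_w * overlap
        start = end
    return energy_w_min / 60.0 / 1000.0


def shelf_temperature_at(cycle: LyoCycle, t_min: float) -> float:
    """Shelf temperature (degC) at time t; clamps at the final setpoint."""
    if t_min < 0:
        raise ValueError("t must be non-negative")
    segs = cycle._segments()
    for t0, t1, temp0, temp1 in segs:
        if t_min < t1:
            if t1 == t0:
                return temp1
            return temp0 + (temp1 - temp0) * (t_min - t0) / (t1 - t0)
    return segs[-1][3] if segs else cycle.steps[-1].setpoint_c


def fractional_cycle_time(t_min: float, mode: str, *, full_time_min: float | None = None,
                          secondary_hold_min: float = 0.0,
                          convergence_time_min: float | None = None,
                          empirical_factor: float = 1.0) -> tuple[float, float]:
    """Normalized cycle time for comparing partial runs across technologies.

    mvd: t / (full cycle time - secondary-drying hold); lyo: t / time to
    thermocouple convergence.  ``empirical_factor`` multiplies the raw
    fraction to absorb tray-to-tray heat-transfer differences (default 1).
    Returns (raw, reported) where reported is rounded half-up to 2 decimals.
    """
    if mode == "mvd":
        if full_time_min is None:
            raise ValueError("mvd mode requires full_time_min")
        denom = full_time_min - secondary_hold_min
    elif mode == "lyo":
        if convergence_time_min is None:
            raise ValueError("lyo mode requires convergence_time_min")
        denom = convergence_time_min
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'mvd' or 'lyo'")
    if denom <= 0:
        raise ValueError("normalization denominator must be positive")
    raw = empirical_factor * t_min / denom
    if raw > 1.0:
        warnings.warn("fractional cycle time exceeds 1", stacklevel=2)
    import decimal
    reported = float(decimal.Decimal(raw).quantize(decimal.Decimal("0.01"),
                                                   rounding=decimal.ROUND_HALF_UP))
    return raw, reported


def percent_reduction(reference_h: float, test_h: float) -> float:
    """Percent reduction of ``test`` relative to ``reference`` durations."""
    if reference_h <= 0:
        raise ValueError("reference duration must be positive")
    return 100.0 * (reference_h - test_h) / reference_h


# ---------------------------------------------------------------------------
# file I/O and shipped fixtures


def read_microwave_schedule(path: str | Path, name: str = "") -> MicrowaveCycle:
    """Read a microwave schedule from delimited text (see MVD_SCHEDULE_COLUMNS)."""
    df = pd.read_csv(path)
    missing = set(MVD_SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule {path} missing columns: {sorted(missing)}")
    steps = tuple(
        PowerStep(row.duration_min, int(row.n_magnetrons), row.power_per_magnetron_W,
                  row.vacuum_lo_mTorr, row.vacuum_hi_mTorr)
        for row in df.itertuples()
    )
    return MicrowaveCycle(steps, name or Path(path).stem)


def read_lyo_schedule(path: str | Path, name: str = "") -> LyoCycle:
    """Read a lyophilizer schedule from delimited text (see LYO_SCHEDULE_COLUMNS)."""
    df = pd.read_csv(path)
    missing = set(LYO_SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule {path} missing columns: {sorted(missing)}")
    steps = tuple(
        LyoStep(row.setpoint_C, row.ramp_C_per_min, row.hold_min, row.vacuum_mTorr)
        for row in df.itertuples()
    )
    return LyoCycle(steps, name or Path(path).stem)


_BUILTIN_MVD = {"mvd_full", "mvd_visualization", "mvd_protein",
                "mvd_terminal_temp", "mvd_ssa"}
_BUILTIN_LYO = {"lyo_benchmark", "lyo_protein"}


def load_builtin_cycle(name: str) -> MicrowaveCycle | LyoCycle:
    """Load one of the shipped benchmark cycles by name."""
    if name not in _BUILTIN_MVD | _BUILTIN_LYO:
        raise ValueError(
            f"unknown builtin cycle {name!r}; available: "
            f"{sorted(_BUILTIN_MVD | _BUILTIN_LYO)}")
    ref = resources.files("mvdry").joinpath(f"data/schedules/{name}.csv")
    with resources.as_file(ref) as path:
        if name in _BUILTIN_MVD:
            return read_microwave_schedule(path, name)
        return read_lyo_schedule(path, name)
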