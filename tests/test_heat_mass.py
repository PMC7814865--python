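"""Heat/mass-transfer operations and the steady-state energy-balance solver."""

import numpy as np
import pytest

from mvdry import (HeatTransferParams, MassTransferParams, VialGeometry,
                   absorbed_microwave_per_vial, combine_kv,
                   conductive_heat_flux, dried_layer_resistance,
                   driving_force_increase, invert_ice_vapor_pressure,
                   microwave_power_dissipated, radiative_flux,
                   solve_steady_state, sublimation_rate, total_heat_flux)
from mvdry.heat_mass import energy_balance_residual
from mvdry.thermo import DEFAULT_ICE


class TestSublimationRate:
    def test_microwave_driving_force(self):
        """127 mTorr across a unit resistance and 1 cm^2 gives 0.127 g/h."""
        assert sublimation_rate(1.0, 0.187, 0.060, 1.0) == pytest.approx(0.127)

    def test_zero_driving_force(self):
        assert sublimation_rate(1.0, 0.1, 0.1, 1.0) == 0.0

    def test_linear_in_area(self):
        assert sublimation_rate(2.0, 0.187, 0.060, 1.0) == \
            pytest.approx(2 * sublimation_rate(1.0, 0.187, 0.060, 1.0))

    def test_condensation_regime_returns_negative(self):
        assert sublimation_rate(1.0, 0.05, 0.10, 1.0) < 0

    def test_invalid_resistance(self):
        with pytest.raises(ValueError):
            sublimation_rate(1.0, 0.1, 0.05, 0.0)


class TestDrivingForce:
    def test_mvd_vs_lyo_increase(self):
        """(187-60) vs (135-40) mTorr is a 33.7% larger driving force."""
        assert driving_force_increase(187, 60, 135, 40) == pytest.approx(33.7, abs=0.05)

    def test_identical_pairs(self):
        assert driving_force_increase(187, 60, 187, 60) == 0.0

    def test_hand_value(self):
        assert driving_force_increase(200, 100, 150, 100) == pytest.approx(100.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            driving_force_increase(1, 0, 1, 1)


class TestDriedLayerResistance:
    def test_zero_thickness_gives_r0(self, mass_params):
        assert dried_layer_resistance(0.0, mass_params) == mass_params.R0

    def test_hand_value(self):
        p = MassTransferParams(R0=1.4, A1=16.0, A2=0.0)
        assert dried_layer_resistance(0.5, p) == pytest.approx(9.4)

    def test_constant_when_a1_zero(self):
        p = MassTransferParams(R0=2.0, A1=0.0, A2=0.0)
        assert dried_layer_resistance(1.0, p) == 2.0

    def test_non_decreasing_in_thickness(self):
        p = MassTransferParams(R0=1.4, A1=16.0, A2=3.0)
        l = np.linspace(0, 1, 200)
        r = np.array([dried_layer_resistance(x, p) for x in l])
        assert np.all(np.diff(r) >= 0)

    def test_negative_thickness_rejected(self, mass_params):
        with pytest.raises(ValueError):
            dried_layer_resistance(-0.1, mass_params)


class TestHeatFluxes:
    def test_conductive_hand_value(self):
        assert conductive_heat_flux(20.0, 3e-4, 268.0, 238.0) == pytest.approx(0.18)

    def test_conductive_zero_and_linearity(self):
        assert conductive_heat_flux(20.0, 3e-4, 250.0, 250.0) == 0.0
        assert conductive_heat_flux(20.0, 3e-4, 260.0, 240.0) == \
            pytest.approx(2 * conductive_heat_flux(20.0, 3e-4, 250.0, 240.0))

    def test_combine_kv(self):
        assert combine_kv(0, 0, 0) == 0
        assert combine_kv(5, 2, 8) == 15
        assert combine_kv(8, 5, 2) == combine_kv(5, 2, 8)

    def test_radiative_hand_value(self):
        assert radiative_flux(3e-4, 0.9, 298.15, 236.15) == \
            pytest.approx(0.0733, abs=1e-4)

    def test_radiative_antisymmetric(self):
        assert radiative_flux(3e-4, 0.9, 240.0, 260.0) == \
            pytest.approx(-radiative_flux(3e-4, 0.9, 260.0, 240.0))

    def test_microwave_volumetric_dissipation(self):
        assert microwave_power_dissipated(1.0, 2.0, 0.1, 2.45e9, 1.0) == \
            pytest.approx(4.9e8)
        assert microwave_power_dissipated(1.0, 2.0, 0.1, 2.45e9, 0.0) == 0.0
        # quadratic in the field strength
        assert microwave_power_dissipated(1.0, 2.0, 0.1, 2.45e9, 2.0) == \
            pytest.approx(4 * microwave_power_dissipated(1.0, 2.0, 0.1, 2.45e9, 1.0))

    def test_absorbed_per_vial(self):
        assert absorbed_microwave_per_vial(1600, 0.25, 224) == \
            pytest.approx(1.786, abs=1e-3)
        assert absorbed_microwave_per_vial(1600, 0.0, 224) == 0.0
        assert absorbed_microwave_per_vial(1600, 0.25, 224, self_mod=0.5) == \
            pytest.approx(absorbed_microwave_per_vial(1600, 0.25, 224) / 2)

    def test_total_flux_is_sum(self):
        assert total_heat_flux(0, 0, 0, 0) == 0
        assert total_heat_flux(0.18, 0, 0.073, 1.79) == pytest.approx(2.043)
        # the microwave-free limit is the conventional lyophilization flux
        assert total_heat_flux(0.18, 0, 0.073, 0.0) == \
            pytest.approx(0.18 + 0.073)


def _grid_oracle(geometry, hp, rp, pc, mw, scale=1.0):
    """Brute-force energy-balance root: argmin |residual| on a 0.001 K grid,
    with the physics recomputed independently of the solver."""
    t = np.arange(180.0, 273.0, 0.001)
    pi = DEFAULT_ICE.prefactor_torr * np.exp(-DEFAULT_ICE.activation_K / t)
    kv = hp.Kc + hp.shelf_radiation_coeff * hp.shelf_emissivity + hp.Kg
    q = scale * (kv * geometry.outer_area_m2 * (hp.shelf_temperature_K - t)
                 + geometry.outer_area_m2 * hp.vial_top_emissivity
                 * 5.670374419e-8 * (hp.lid_temperature_K ** 4 - t ** 4)) + mw
    demand = 2840.0 * geometry.product_area_cm2 * (pi - pc) / rp / 3600.0
    return t[np.argmin(np.abs(q - demand))]


class TestSteadyStateSolver:
    def test_zero_heat_limit_recovers_chamber_equilibrium(self, geometry,
                                                          mass_params, zero_heat):
        """With every heat source off the front settles where the ice vapor
        pressure equals the chamber pressure."""
        tp, rate = solve_steady_state(geometry, zero_heat, mass_params, 0.060)
        assert tp == pytest.approx(invert_ice_vapor_pressure(0.060), abs=1e-6)
        assert abs(rate) < 1e-9

    def test_residual_below_tolerance(self, geometry, mass_params, lyo_heat):
        tp, _ = solve_steady_state(geometry, lyo_heat, mass_params, 0.040)
        res = energy_balance_residual(tp, geometry, lyo_heat, mass_params.R0, 0.040)
        assert abs(res) < 1e-9

    def test_agrees_with_grid_search_oracle(self, geometry):
        rng = np.random.default_rng(42)
        for _ in range(20):
            hp = HeatTransferParams(
                Kc=float(rng.uniform(0.5, 15.0)), Kg=float(rng.uniform(0.0, 4.0)),
                shelf_emissivity=float(rng.uniform(0.0, 1.0)),
                vial_top_emissivity=float(rng.uniform(0.0, 1.0)),
                shelf_temperature_K=float(rng.uniform(233.0, 268.0)),
                lid_temperature_K=float(rng.uniform(233.0, 298.0)))
            mp = MassTransferParams(R0=float(rng.uniform(0.5, 3.0)),
                                    A1=0.0, A2=0.0)
            pc = float(rng.uniform(0.03, 0.2))
            mw = float(rng.uniform(0.0, 1.0))
            tp, _ = solve_steady_state(geometry, hp, mp, pc, microwave_w=mw)
            oracle = _grid_oracle(geometry, hp, mp.R0, pc, mw)
            assert tp == pytest.approx(oracle, abs=0.01)

    def test_monotone_in_microwave_power(self, geometry, mass_params, zero_heat):
        powers = np.linspace(0.05, 1.5, 8)
        results = [solve_steady_state(geometry, zero_heat, mass_params, 0.060,
                                      microwave_w=w) for w in powers]
        tps = [r[0] for r in results]
        rates = [r[1] for r in results]
        assert np.all(np.diff(tps) > 0)
        assert np.all(np.diff(rates) > 0)

    def test_rate_monotone_in_resistance(self, geometry, lyo_heat):
        rates = []
        for r0 in (0.7, 1.4, 2.8, 5.6):
            mp = MassTransferParams(R0=r0, A1=0.0)
            rates.append(solve_steady_state(geometry, lyo_heat, mp, 0.040)[1])
        assert np.all(np.diff(rates) < 0)

    def test_no_root_reports_both_endpoints(self, geometry, mass_params, zero_heat):
        with pytest.raises(RuntimeError, match="residual"):
            # 50 W into one vial can never be balanced below the melt bracket
            solve_steady_state(geometry, zero_heat, mass_params, 0.060,
                               microwave_w=50.0)


class TestGeometryInvariants:
    def test_fill_height_consistency(self):
        g = VialGeometry(fill_volume_ml=0.7, product_area_m2=1.767e-4)
        assert g.fill_height_m == pytest.approx(0.7e-6 / 1.767e-4, rel=1e-9)

    def test_product_area_cannot_exceed_vial(self):
        with pytest.raises(ValueError):
            VialGeometry(outer_area_m2=1e-4, product_area_m2=2e-4)
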