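"""Elementary fluxes, unit conversions and right-hand-side structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oatkin import (
    AVOGADRO,
    AlbuminParameters,
    CompartmentGeometry,
    EffluxParameters,
    FittingState,
    StandardState,
    TransportParameters,
    UptakeCase,
    UremicFactors,
    complex_binding_rate,
    efflux_flux,
    fitting_model_rhs,
    membrane_to_volume_factor,
    standard_model_rhs,
    uptake_flux,
)
from oatkin.model import InvalidGeometryError, InvalidStateError


class TestMembraneToVolumeFactor:
    def test_default_membrane_over_well(self):
        # 0.32 cm² over 100 µL
        u = membrane_to_volume_factor(3.2e7, 1e-4)
        assert u == pytest.approx(5.3138e-7, rel=1e-4)

    def test_proportional_in_area_inverse_in_volume(self):
        u = membrane_to_volume_factor(3.2e7, 1e-4)
        assert membrane_to_volume_factor(1.6e7, 1e-4) == pytest.approx(u / 2)
        assert membrane_to_volume_factor(3.2e7, 2e-4) == pytest.approx(u / 2)
        assert membrane_to_volume_factor(3.2e-3, 1e-4) > 0.0

    @pytest.mark.parametrize("area,volume", [(0.0, 1e-4), (3.2e7, 0.0), (-1.0, 1e-4)])
    def test_invalid_geometry(self, area, volume):
        with pytest.raises(InvalidGeometryError):
            membrane_to_volume_factor(area, volume)


class TestUptakeFlux:
    def test_mass_action_at_experiment_start(self, transport):
        j = uptake_flux(UptakeCase.MASS_ACTION, 25.0, 1.15e7, transport)
        assert j == pytest.approx(5.03125e3, rel=1e-12)

    @pytest.mark.parametrize("case", list(UptakeCase))
    def test_no_substrate_no_flux(self, case):
        params = TransportParameters(uptake_case=case, vmax_case=1e-3, km_case=50.0)
        assert uptake_flux(case, 0.0, 1.15e7, params) == 0.0

    def test_half_saturation_case3(self):
        params = TransportParameters(
            uptake_case=UptakeCase.MM_TIMES_OAT1, vmax_case=1e-3, km_case=50.0
        )
        j = uptake_flux(UptakeCase.MM_TIMES_OAT1, 50.0, 1.15e7, params)
        assert j == pytest.approx(0.5e-3 * 1.15e7)

    def test_unknown_case_rejected(self, transport):
        with pytest.raises(ValueError):
            uptake_flux(7, 25.0, 1.15e7, transport)

    def test_mm_case_requires_km(self, transport):
        with pytest.raises(ValueError):
            uptake_flux(UptakeCase.MICHAELIS_MENTEN, 25.0, 1.15e7, transport)
        with pytest.raises(ValueError):
            TransportParameters(uptake_case=2, vmax_case=1e-3, km_case=0.0)

    @given(c=st.floats(0.0, 1e4), case=st.sampled_from(list(UptakeCase)))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_substrate_and_bounded(self, c, case):
        params = TransportParameters(
            kf_uptake=1.75e-5, uptake_case=case, vmax_case=1e-3, km_case=50.0
        )
        j = uptake_flux(case, c, 1.15e7, params)
        j2 = uptake_flux(case, c * 1.5 + 1.0, 1.15e7, params)
        assert j >= 0.0
        assert j2 >= j
        if case is UptakeCase.MICHAELIS_MENTEN:
            assert j <= params.vmax_case


class TestEffluxFlux:
    def test_half_saturation(self):
        assert efflux_flux(69.0, EffluxParameters()) == pytest.approx(12000.0)

    def test_zero_and_saturation(self):
        p = EffluxParameters()
        assert efflux_flux(0.0, p) == 0.0
        assert efflux_flux(1e9, p) == pytest.approx(24000.0, rel=1e-6)
        assert efflux_flux(1e4, p) < 24000.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidStateError):
            efflux_flux(-1.0, EffluxParameters())


class TestComplexBindingRate:
    def test_half_saturation_in_albumin(self):
        assert complex_binding_rate(97.92, AlbuminParameters()) == pytest.approx(1.35)

    def test_zero_albumin(self):
        assert complex_binding_rate(0.0, AlbuminParameters()) == 0.0

    def test_one_millimolar(self):
        assert complex_binding_rate(1000.0, AlbuminParameters()) == pytest.approx(
            2.4592, rel=1e-4
        )

    def test_reduction_factor_scales_linearly(self):
        full = complex_binding_rate(1000.0, AlbuminParameters(), f1=1.0)
        assert complex_binding_rate(1000.0, AlbuminParameters(), f1=1e-5) == pytest.approx(
            1e-5 * full
        )


class TestFittingModelRhs:
    def _mass_weights(self, geom):
        v = 1e-6 * AVOGADRO
        return np.array(
            [geom.well_volume_l * v, 0.0, geom.basolateral_area_um2, geom.cell_volume_l * v]
        )

    def test_initial_well_depletion_rate(self, transport, geometry):
        state = FittingState(is_well=25.0, oat1_free=1.15e7)
        dy = fitting_model_rhs(state, transport, EffluxParameters(), geometry)
        assert dy[0] == pytest.approx(-2.6735e-3, rel=1e-4)

    def test_empty_system_is_stationary(self, transport, geometry):
        state = FittingState(is_well=0.0, oat1_free=1.15e7)
        dy = fitting_model_rhs(state, transport, EffluxParameters(), geometry)
        assert np.all(dy == 0.0)

    def test_is_and_carrier_conservation_by_construction(self, transport, geometry):
        state = FittingState(is_well=13.0, oat1_free=5e6, oat1_is=6.5e6, is_cell=42.0)
        dy = fitting_model_rhs(state, transport, EffluxParameters(), geometry)
        # total IS molecules: well + membrane-bound + cell
        weights = self._mass_weights(geometry)
        weights[2] = geometry.basolateral_area_um2
        assert abs(np.dot(dy, weights)) <= 1e-9 * np.max(np.abs(dy) * weights)
        # total carrier
        assert dy[1] + dy[2] == pytest.approx(0.0, abs=1e-20)

    def test_negative_state_rejected(self, transport, geometry):
        with pytest.raises(InvalidStateError):
            fitting_model_rhs(
                np.array([-1.0, 1.15e7, 0.0, 0.0]), transport, EffluxParameters(), geometry
            )


class TestStandardModelRhs:
    def _rhs(self, y, factors=UremicFactors(1.0, 1.0)):
        return standard_model_rhs(
            y, TransportParameters(), EffluxParameters(), AlbuminParameters(),
            CompartmentGeometry(), factors,
        )

    def test_identity_factors_match_unmodified_model(self):
        y = StandardState(is_b=25.0, hsa=1000.0, complex=3.0, oat1_free=1e7,
                          oat1_is=1.5e6, is_cell=12.0, is_d=1.0)
        base = standard_model_rhs(
            y, TransportParameters(), EffluxParameters(), AlbuminParameters(),
            CompartmentGeometry(),
        )
        np.testing.assert_array_equal(base, self._rhs(y))

    def test_uptake_requires_complex(self):
        # free IS alone cannot engage the carrier: with no complex formed yet
        # the carrier occupancy does not change
        y = StandardState(is_b=25.0, hsa=1000.0, complex=0.0, oat1_free=1.15e7)
        dy = self._rhs(y)
        assert dy[3] == 0.0 and dy[4] == 0.0

    @given(
        st.lists(st.floats(0.0, 1e3), min_size=3, max_size=3),
        st.floats(0.0, 1.15e7),
        st.floats(0.0, 500.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_albumin_and_carrier_conserved_at_any_state(self, concs, oat_bound, is_cell):
        is_b, hsa, cpx = concs
        y = StandardState(is_b=is_b, hsa=hsa, complex=cpx,
                          oat1_free=1.15e7 - oat_bound, oat1_is=oat_bound,
                          is_cell=is_cell, is_d=0.0)
        dy = self._rhs(y)
        assert dy[1] + dy[2] == pytest.approx(0.0, abs=1e-12 * max(1.0, abs(dy[1])))
        assert dy[3] + dy[4] == pytest.approx(0.0, abs=1e-9)

    def test_total_is_molecules_conserved_by_construction(self, geometry):
        y = StandardState(is_b=100.0, hsa=900.0, complex=50.0, oat1_free=8e6,
                          oat1_is=3.5e6, is_cell=200.0, is_d=30.0)
        dy = self._rhs(y)
        v = 1e-6 * AVOGADRO
        weights = np.array([
            geometry.well_volume_l * v, 0.0, geometry.well_volume_l * v,
            0.0, geometry.basolateral_area_um2,
            geometry.cell_volume_l * v, geometry.dialysate_volume_l * v,
        ])
        scale = np.max(np.abs(dy) * np.abs(weights))
        assert abs(np.dot(dy, weights)) <= 1e-9 * scale

    def test_negative_state_rejected(self):
        y = np.array([25.0, 1000.0, -0.1, 1.15e7, 0.0, 0.0, 0.0])
        with pytest.raises(InvalidStateError):
            self._rhs(y)


class TestParameterValidation:
    def test_geometry_must_be_positive(self):
        with pytest.raises(InvalidGeometryError):
            CompartmentGeometry(cell_volume=0.0)

    def test_uremic_factors_bounded(self):
        with pytest.raises(ValueError):
            UremicFactors(1.5, 0.5)
        with pytest.raises(ValueError):
            UremicFactors(0.5, -0.1)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            TransportParameters(kf_uptake=-1e-5)
        with pytest.raises(ValueError):
            EffluxParameters(vmax_efflux=-1.0)
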