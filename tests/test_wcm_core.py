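"""Forward water-cloud model and its closed-form inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricewcm.wcm_core import (
    CanopyLayer,
    CanopyWater,
    DegenerateModelError,
    InvalidLayerError,
    InversionCoeffs,
    InversionRangeWarning,
    RadarConfig,
    SaturationError,
    Scale,
    ScaleMismatchError,
    WCMParams,
    derive_inversion_coeffs,
    forward_sigma0_flooded,
    forward_sigma0_full,
    forward_sigma0_full_db,
    invert_total_canopy_water,
    layer_unit_volume_water,
    soil_backscatter,
    two_way_attenuation,
)


class TestLayerWater:
    @pytest.mark.parametrize(
        "m_wet, m_dry, n, h, expected",
        [
            (0.0115, 0.0100, 300, 0.15, 3.0),
            (0.020, 0.020, 250, 0.5, 0.0),  # no water at all
            (0.030, 0.010, 200, 0.15, 26.666666666666668),
        ],
    )
    def test_unit_volume_water(self, m_wet, m_dry, n, h, expected):
        layer = CanopyLayer(h=h, m_wet=m_wet, m_dry=m_dry, n=n)
        assert layer_unit_volume_water(layer) == pytest.approx(expected, rel=1e-9)

    def test_areal_water_is_unit_volume_times_height(self):
        layer = CanopyLayer(h=0.15, m_wet=0.0115, m_dry=0.0100, n=300)
        assert layer.areal_water == pytest.approx(0.45)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(h=0.0, m_wet=0.02, m_dry=0.01, n=100),
            dict(h=0.5, m_wet=0.01, m_dry=0.02, n=100),  # dry exceeds wet
            dict(h=0.5, m_wet=0.02, m_dry=0.01, n=0),
        ],
    )
    def test_invalid_layers_rejected(self, kwargs):
        with pytest.raises(InvalidLayerError):
            CanopyLayer(**kwargs)

    def test_canopy_water_from_layers_ties_areal_to_heights(self):
        panicle = CanopyLayer(h=0.15, m_wet=0.0115, m_dry=0.0100, n=300)
        stem = CanopyLayer(h=0.70, m_wet=0.040, m_dry=0.020, n=300)
        water = CanopyWater.from_layers(panicle, stem)
        assert water.w1h1 == pytest.approx(water.W1 * panicle.h)
        assert water.w2h2 == pytest.approx(water.W2 * stem.h)
        assert water.total_areal == pytest.approx(water.w1h1 + water.w2h2)


class TestAttenuation:
    @pytest.mark.parametrize(
        "D, water, theta, expected",
        [
            (0.0, 3.0, 50.0, 1.0),
            (0.5, 1.0, 60.0, math.exp(-2.0)),
            (0.25, 2.0, 50.0, 0.21103657340356870),
        ],
    )
    def test_closed_form(self, D, water, theta, expected):
        assert two_way_attenuation(D, water, theta) == pytest.approx(expected, rel=1e-9)

    def test_rejects_grazing_incidence(self):
        with pytest.raises(ValueError):
            two_way_attenuation(0.5, 1.0, 90.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        D=st.floats(0.0, 2.0),
        w1=st.floats(0.0, 4.0),
        w2=st.floats(0.0, 4.0),
        theta=st.floats(0.0, 80.0),  # exponent stays clear of exp underflow
    )
    def test_bounded_and_multiplicative_across_layers(self, D, w1, w2, theta):
        t_both = two_way_attenuation(D, w1 + w2, theta)
        assert 0.0 < t_both <= 1.0
        t_split = two_way_attenuation(D, w1, theta) * two_way_attenuation(D, w2, theta)
        assert t_both == pytest.approx(t_split, rel=1e-9)


class TestSoilAndFullModel:
    @pytest.mark.parametrize(
        "A, B, ms, expected",
        [(0.1, 2.0, 0.0, 0.1), (0.1, 2.0, 0.25, 0.16487212707001284), (0.0, 5.0, 0.9, 0.0)],
    )
    def test_soil_backscatter(self, A, B, ms, expected):
        assert soil_backscatter(A, B, ms) == pytest.approx(expected, rel=1e-9)

    def _params(self, **kw):
        base = dict(C=0.09, D=0.4, sigma0_bg=0.0, scale=Scale.LINEAR, soil_A=0.05, soil_B=1.0, ms=0.3)
        base.update(kw)
        return WCMParams(**base)

    def test_bare_soil_limit(self):
        p = self._params()
        water = CanopyWater.from_areal(0.0, 0.0)
        assert forward_sigma0_full(p, water, 50.0) == pytest.approx(0.05 * math.exp(0.3))

    def test_saturation_limit_is_canopy_asymptote(self):
        p = self._params()
        water = CanopyWater.from_areal(50.0, 50.0)
        assert forward_sigma0_full(p, water, 50.0) == pytest.approx(0.09, rel=1e-6)

    def test_reference_point_and_db_variant(self):
        # frozen from an independent evaluation of the closed form
        p = self._params()
        water = CanopyWater.from_areal(0.5, 2.5)
        assert forward_sigma0_full(p, water, 50.0) == pytest.approx(0.08946200615721589, rel=1e-12)
        assert forward_sigma0_full_db(p, water, 50.0) == pytest.approx(-10.48361367137655, rel=1e-12)

    def test_full_model_requires_linear_scale_and_soil(self):
        with pytest.raises(ScaleMismatchError):
            forward_sigma0_full(
                WCMParams(C=-10.0, D=0.4, sigma0_bg=-13.0, scale=Scale.DB, soil_A=0.1, soil_B=1.0, ms=0.2),
                CanopyWater.from_areal(0.5, 1.0),
                50.0,
            )
        with pytest.raises(ValueError):
            forward_sigma0_full(
                WCMParams(C=0.09, D=0.4, sigma0_bg=0.0, scale=Scale.LINEAR),
                CanopyWater.from_areal(0.5, 1.0),
                50.0,
            )

    def test_constant_background_reproduces_flooded_model(self):
        # replacing A*exp(B*ms) by a constant sigma0_bg collapses the full
        # model onto the flooded-field form exactly
        bg = 0.05 * math.exp(0.3)
        p_full = self._params()
        p_flood = WCMParams(C=0.09, D=0.4, sigma0_bg=bg, scale=Scale.LINEAR)
        for total in (0.0, 0.3, 1.7, 6.0):
            water = CanopyWater.from_areal(total * 0.2, total * 0.8)
            assert forward_sigma0_full(p_full, water, 50.0) == pytest.approx(
                forward_sigma0_flooded(p_flood, total, 50.0), rel=1e-12
            )


class TestFloodedModelAndInversion:
    P = WCMParams(C=-10.57, D=0.7533, sigma0_bg=-13.0, scale=Scale.DB)

    def test_limits(self):
        assert forward_sigma0_flooded(self.P, 0.0, 50.0) == pytest.approx(-13.0)
        assert forward_sigma0_flooded(self.P, 1e6, 50.0) == pytest.approx(-10.57)

    def test_reference_point(self):
        # frozen from an independent evaluation of the closed form
        assert forward_sigma0_flooded(self.P, 1.0, 50.0) == pytest.approx(-10.80317588004463, rel=1e-12)

    def test_derive_coeffs_closed_form(self):
        p = WCMParams(C=1.0, D=0.4, sigma0_bg=0.2, scale=Scale.LINEAR)
        co = derive_inversion_coeffs(p, 0.0)
        assert co.b == pytest.approx(1.25)
        assert co.a == pytest.approx(1.25 * math.log(0.8), rel=1e-12)
        # C - sigma0_bg = 1 zeroes the offset
        co2 = derive_inversion_coeffs(WCMParams(C=1.2, D=0.7, sigma0_bg=0.2, scale=Scale.LINEAR), 35.0)
        assert co2.a == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_model_rejected(self):
        with pytest.raises(DegenerateModelError):
            derive_inversion_coeffs(WCMParams(C=-13.0, D=0.5, sigma0_bg=-10.0, scale=Scale.DB), 50.0)

    def test_inversion_reference_point(self):
        co = InversionCoeffs(a=-1.58, b=0.6638, C=-10.57, scale=Scale.DB)
        assert invert_total_canopy_water(-10.63, co) == pytest.approx(0.2875420337853063, rel=1e-9)

    def test_saturation_raises(self):
        co = InversionCoeffs(a=-1.58, b=0.6638, C=-10.57)
        with pytest.raises(SaturationError):
            invert_total_canopy_water(-10.57, co)

    def test_below_range_flagged_not_clipped(self):
        co = InversionCoeffs(a=-1.58, b=0.6638, C=-10.57)
        # sigma0 with C - sigma0 = exp(a/b) sits exactly at zero water
        s_zero = co.C - math.exp(co.a / co.b)
        assert invert_total_canopy_water(s_zero, co) == pytest.approx(0.0, abs=1e-12)
        with pytest.warns(InversionRangeWarning):
            val = invert_total_canopy_water(s_zero - 1.0, co)
        assert val < 0.0

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        C=st.floats(-20.0, 5.0),
        gap=st.floats(0.1, 15.0),
        D=st.floats(0.05, 3.0),
        theta=st.floats(0.0, 80.0),
        exponent=st.floats(0.0, 8.0),
    )
    def test_inversion_is_exact_inverse_of_forward(self, C, gap, D, theta, exponent):
        # parameterised by the two-way attenuation exponent so the canopy
        # spans bare water up to deep saturation (tau^2 down to e^-8) while
        # C - sigma0 stays representable in floating point
        total = exponent * math.cos(math.radians(theta)) / (2.0 * D)
        p = WCMParams(C=C, D=D, sigma0_bg=C - gap, scale=Scale.DB)
        co = derive_inversion_coeffs(p, theta)
        s = forward_sigma0_flooded(p, total, theta)
        assert invert_total_canopy_water(s, co) == pytest.approx(total, abs=1e-8)

    def test_monotone_increasing_in_water_and_sigma0(self):
        totals = np.linspace(0.0, 6.0, 200)
        s = np.array([forward_sigma0_flooded(self.P, t, 50.0) for t in totals])
        assert np.all(np.diff(s) > 0)
        co = derive_inversion_coeffs(self.P, 50.0)
        sig = np.linspace(-12.9, -10.6, 200)
        w = np.array([invert_total_canopy_water(x, co) for x in sig])
        assert np.all(np.diff(w) > 0)

    def test_zero_attenuation_limit_pins_background(self):
        tiny = WCMParams(C=-10.57, D=1e-12, sigma0_bg=-13.0, scale=Scale.DB)
        for total in (0.0, 1.0, 5.0):
            assert forward_sigma0_flooded(tiny, total, 50.0) == pytest.approx(-13.0)


class TestTypesAndIO:
    def test_radar_config_invariants(self):
        RadarConfig()  # defaults are valid
        with pytest.raises(ValueError):
            RadarConfig(incidence_deg=95.0)
        with pytest.raises(ValueError):
            RadarConfig(resolution_m=0.0)

    def test_params_json_round_trip(self, tmp_path):
        p = WCMParams(C=-10.57, D=0.7533, sigma0_bg=-13.0, scale=Scale.DB,
                      soil_A=0.1, soil_B=2.0, ms=0.25)
        path = tmp_path / "wcm.json"
        p.to_json(path, theta_deg=50.0)
        q = WCMParams.from_json(path)
        assert q == p
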