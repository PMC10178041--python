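import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from poddry.errors import DomainError
from poddry.properties import (
    equivalent_sphere_diameter,
    hot_air_properties,
    kernel_material,
    pod_material,
    shell_material,
    transfer_coefficients,
)


class TestHotAirProperties:
    def test_polynomials_at_42C(self):
        """Air properties at the drying temperature equal the quadratic fits
        evaluated by hand."""
        air = hot_air_properties(42.0)
        assert air.rho_a == pytest.approx(8.666e-6 * 42**2 - 4.318e-3 * 42 + 1.288, rel=1e-12)
        assert air.c_a == pytest.approx(4.834e-4 * 42**2 - 2.218e-2 * 42 + 1007, rel=1e-12)
        assert air.k_a == pytest.approx(-2.401e-8 * 42**2 + 7.554e-5 * 42 + 2.364e-2, rel=1e-12)
        assert air.mu_a == pytest.approx(-3.238e-11 * 42**2 + 4.839e-8 * 42 + 1.73e-5, rel=1e-12)
        assert air.D_a == pytest.approx(3.229e-10 * 42**2 + 1.577e-7 * 42 + 2.089e-5, rel=1e-12)
        assert air.rho_a == pytest.approx(1.12193, abs=1e-5)
        assert air.k_a == pytest.approx(0.026770, abs=1e-6)

    def test_intercepts_at_0C(self):
        air = hot_air_properties(0.0, va=0.5, RH=0.1)
        assert air.rho_a == 1.288
        assert air.va == 0.5 and air.RH == 0.1

    def test_positive_and_deterministic_over_range(self):
        for Ta in np.linspace(0, 100, 21):
            a1 = hot_air_properties(float(Ta))
            a2 = hot_air_properties(float(Ta))
            assert a1 == a2  # bit-identical re-evaluation
            assert min(a1.rho_a, a1.c_a, a1.k_a, a1.mu_a, a1.D_a) > 0

    @pytest.mark.parametrize("Ta", [-5.0, 120.0])
    def test_out_of_range_temperature_rejected(self, Ta):
        with pytest.raises(DomainError, match=r"\[0, 100\]"):
            hot_air_properties(Ta)


class TestMaterialLaws:
    def test_conductivity_examples(self):
        assert shell_material().conductivity(0.0) == pytest.approx(0.07753)
        assert kernel_material().conductivity(0.74) == pytest.approx(0.32528 * 0.74 + 0.12559)
        assert shell_material().conductivity(1.24) == pytest.approx(0.17062 * 1.24 + 0.07753)

    def test_specific_heat_examples_in_SI(self):
        assert kernel_material().specific_heat(0.0) == pytest.approx(1153.07)
        assert kernel_material().specific_heat(0.74) == pytest.approx((1.96152 * 0.74 + 1.15307) * 1000)
        assert shell_material().specific_heat(1.24) == pytest.approx((4.04506 * 1.24 + 2.05226) * 1000)

    def test_clamped_above_initial_moisture(self):
        shell = shell_material()
        assert shell.conductivity(5.0) == shell.conductivity(shell.M0)

    def test_negative_moisture_rejected(self):
        with pytest.raises(DomainError):
            shell_material().conductivity(-0.1)
        with pytest.raises(DomainError):
            kernel_material().specific_heat(-1e-9)

    @given(M=st.floats(0.0, 0.74))
    def test_midpoint_linearity(self, M):
        """Linear laws: value at the midpoint equals the mean of endpoints."""
        mat = kernel_material()
        mid = mat.specific_heat(M / 2.0)
        assert mid == pytest.approx((mat.specific_heat(0.0) + mat.specific_heat(M)) / 2.0, rel=1e-12)

    def test_pod_mixture_density_is_mass_over_volume(self):
        pod = pod_material()
        fv = 1.0 - (0.005**2 * 0.008) / (0.006**2 * 0.009)
        assert pod.rho == pytest.approx(fv * 560 + (1 - fv) * 1000, rel=1e-4)
        assert pod.D_eff == 5.7512e-10 and pod.M0 == 0.83


class TestTransferCoefficients:
    def test_reynolds_and_film_coefficient_at_reference_state(self):
        """Re and h_T from the correlation chain agree with hand evaluation
        at 42 °C, 0.75 m/s, d = volume-equivalent sphere of the pod."""
        air = hot_air_properties(42.0, va=0.75)
        d = equivalent_sphere_diameter(0.006, 0.009)
        assert d == pytest.approx(0.013737, abs=1e-6)
        tc = transfer_coefficients(air, d)
        Re_hand = 0.75 * air.rho_a * d / air.mu_a
        assert tc.Re == pytest.approx(Re_hand, rel=1e-12)
        assert tc.Re == pytest.approx(600.0, rel=2e-3)
        Nu_hand = 2 + 0.552 * Re_hand**0.53 * (air.mu_a * air.c_a / air.k_a) ** (1 / 3)
        assert tc.h_T == pytest.approx(Nu_hand * air.k_a / d, rel=1e-12)
        assert tc.h_T == pytest.approx(32.6, rel=5e-3)
        assert tc.Sh == pytest.approx(2 + 0.552 * math.sqrt(Re_hand) * tc.Sc ** (1 / 3), rel=1e-12)
        assert tc.h_m == pytest.approx(tc.Sh * air.D_a / d, rel=1e-12)

    def test_pure_diffusion_limit_at_zero_velocity(self):
        air = hot_air_properties(42.0, va=0.0)
        tc = transfer_coefficients(air, 0.01)
        assert tc.Nu == 2.0 and tc.Sh == 2.0

    @given(va=st.floats(0.01, 10.0), dv=st.floats(0.01, 5.0))
    def test_film_coefficients_increase_with_velocity(self, va, dv):
        d = 0.01374
        lo = transfer_coefficients(hot_air_properties(42.0, va=va), d)
        hi = transfer_coefficients(hot_air_properties(42.0, va=va + dv), d)
        assert hi.h_T > lo.h_T and hi.h_m > lo.h_m

    def test_harmonized_exponent_switch(self):
        air = hot_air_properties(42.0, va=0.75)
        sym = transfer_coefficients(air, 0.01374, nu_exponent=0.5)
        assert sym.Nu == pytest.approx(2 + 0.552 * math.sqrt(sym.Re) * sym.Pr ** (1 / 3), rel=1e-12)

    def test_invalid_diameter_rejected(self):
        with pytest.raises(DomainError):
            transfer_coefficients(hot_air_properties(42.0), -0.01)
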