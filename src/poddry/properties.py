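"""Physical property correlations and convective transfer coefficients.

Hot-air properties are quadratic polynomials in the air temperature (°C);
tissue conductivity and specific heat are linear in dry-basis moisture, fitted
from transient-plane-source measurements on shell and kernel tissue.  The
air-side heat and mass transfer coefficients come from Ranz–Marshall-type
Nusselt and Sherwood correlations for a sphere of equivalent diameter ``d``.

All quantities are SI internally; the only non-SI convention retained is the
dry-basis moisture content M (kg water per kg dry matter, written g/g) and
the Celsius argument of the air-property polynomials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import DomainError

KELVIN_OFFSET = 273.15

#: Latent heat of vaporization of water, J/kg.
LATENT_HEAT_VAPORIZATION = 2_256_267.0

# Quadratic coefficients (c2, c1, c0) in air temperature Ta [°C].
_AIR_DENSITY = (8.666e-6, -4.318e-3, 1.288)            # kg/m^3
_AIR_SPECIFIC_HEAT = (4.834e-4, -2.218e-2, 1007.0)     # J/(kg K)
_AIR_CONDUCTIVITY = (-2.401e-8, 7.554e-5, 2.364e-2)    # W/(m K)
_AIR_VISCOSITY = (-3.238e-11, 4.839e-8, 1.73e-5)       # Pa s
_AIR_VAPOR_DIFFUSIVITY = (3.229e-10, 1.577e-7, 2.089e-5)  # m^2/s


def _poly2(coeffs: tuple[float, float, float], x: float) -> float:
    c2, c1, c0 = coeffs
    return (c2 * x + c1) * x + c0


@dataclass(frozen=True)
class AirState:
    """Drying-medium state and derived transport properties.

    Ta is in °C (the property polynomials are Celsius-based); va in m/s;
    RH a fraction.  Derived fields are SI.
    """

    Ta: float
    va: float
    RH: float
    rho_a: float
    c_a: float
    k_a: float
    mu_a: float
    D_a: float

    @property
    def Ta_K(self) -> float:
        return self.Ta + KELVIN_OFFSET


def hot_air_properties(Ta: float, va: float = 0.75, RH: float = 0.08) -> AirState:
    """Evaluate hot-air density, cp, conductivity, viscosity and vapor
    diffusivity at air temperature ``Ta`` (°C).

    Raises :class:`DomainError` if Ta is outside [0, 100] °C, the range over
    which the polynomial fits are physically sensible.
    """
    if not 0.0 <= Ta <= 100.0:
        raise DomainError(
            f"air temperature Ta={Ta!r} °C outside the valid range [0, 100] °C"
        )
    if va < 0:
        raise DomainError(f"air velocity va={va!r} must be non-negative")
    if not 0.0 <= RH <= 1.0:
        raise DomainError(f"relative humidity RH={RH!r} must be a fraction in [0, 1]")
    return AirState(
        Ta=Ta,
        va=va,
        RH=RH,
        rho_a=_poly2(_AIR_DENSITY, Ta),
        c_a=_poly2(_AIR_SPECIFIC_HEAT, Ta),
        k_a=_poly2(_AIR_CONDUCTIVITY, Ta),
        mu_a=_poly2(_AIR_VISCOSITY, Ta),
        D_a=_poly2(_AIR_VAPOR_DIFFUSIVITY, Ta),
    )


@dataclass(frozen=True)
class MaterialModel:
    """One tissue component: density, moisture-dependent k and cp laws,
    effective moisture diffusivity and initial moisture.

    ``k_of_M`` and ``cp_of_M`` are (slope, intercept) pairs; conductivity in
    W/(m·K) per d.b. unit, specific heat in kJ/(kg·K) per d.b. unit (converted
    to J/(kg·K) on evaluation).  Both laws are clamped to M ∈ [0, M0]: the
    fits were made on the drying range and are not extrapolated above the
    initial moisture.
    """

    name: str
    rho: float            # dry-solid density, kg/m^3
    k_of_M: tuple[float, float]
    cp_of_M: tuple[float, float]   # kJ/(kg K)
    D_eff: float          # m^2/s
    M0: float             # initial dry-basis moisture, g/g
    h_g: float = LATENT_HEAT_VAPORIZATION

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise DomainError(f"density must be positive, got {self.rho}")
        if self.D_eff <= 0:
            raise DomainError(f"D_eff must be positive, got {self.D_eff}")

    def _clamp(self, M):
        import numpy as np

        if np.any(np.asarray(M) < 0):
            raise DomainError("dry-basis moisture must be non-negative")
        return np.clip(M, 0.0, self.M0)

    def conductivity(self, M):
        """Thermal conductivity k(M), W/(m·K), clamped to [0, M0]."""
        s, b = self.k_of_M
        return s * self._clamp(M) + b

    def specific_heat(self, M):
        """Specific heat cp(M), J/(kg·K), clamped to [0, M0]."""
        s, b = self.cp_of_M
        return (s * self._clamp(M) + b) * 1000.0


def shell_material() -> MaterialModel:
    """Peanut shell: fibrous, low-density outer hull."""
    return MaterialModel(
        name="shell",
        rho=560.0,
        k_of_M=(0.17062, 0.07753),
        cp_of_M=(4.04506, 2.05226),
        D_eff=1.63249e-10,
        M0=1.24,
    )


def kernel_material() -> MaterialModel:
    """Peanut kernel: dense, protein/oil-rich seed."""
    return MaterialModel(
        name="kernel",
        rho=1000.0,
        k_of_M=(0.32528, 0.12559),
        cp_of_M=(1.96152, 1.15307),
        D_eff=2.91731e-10,
        M0=0.74,
    )


def pod_material(
    shell: MaterialModel | None = None,
    kernel: MaterialModel | None = None,
    shell_volume_fraction: float = 0.38272,
    D_eff: float = 5.7512e-10,
    M0: float = 0.83,
) -> MaterialModel:
    """Homogenized whole-pod material for single-region pod runs.

    Density is the total dry mass over total volume (volume-fraction mix);
    k(M) and cp(M) are dry-mass-weighted mixtures of the component laws.
    The default shell volume fraction corresponds to a 5×8 mm kernel inside
    a 1 mm shell.  D_eff and M0 are the measured whole-pod values.
    """
    shell = shell or shell_material()
    kernel = kernel or kernel_material()
    fv = shell_volume_fraction
    if not 0.0 < fv < 1.0:
        raise DomainError("shell volume fraction must be in (0, 1)")
    rho = fv * shell.rho + (1.0 - fv) * kernel.rho
    w = fv * shell.rho / rho  # dry-mass fraction of shell
    mix = lambda a, b: (w * a[0] + (1 - w) * b[0], w * a[1] + (1 - w) * b[1])
    return MaterialModel(
        name="pod",
        rho=rho,
        k_of_M=mix(shell.k_of_M, kernel.k_of_M),
        cp_of_M=mix(shell.cp_of_M, kernel.cp_of_M),
        D_eff=D_eff,
        M0=M0,
    )


def equivalent_sphere_diameter(a: float, b: float) -> float:
    """Diameter of the sphere with the volume of the spheroid with equatorial
    semi-axis ``a`` and polar semi-axis ``b`` (both m)."""
    if a <= 0 or b <= 0:
        raise DomainError("semi-axes must be positive")
    return 2.0 * (a * a * b) ** (1.0 / 3.0)


@dataclass(frozen=True)
class TransferCoefficients:
    """Air-side convective transfer coefficients and the dimensionless groups
    they derive from.  ``f_s`` is the dimensionless surface-resistance scale
    applied to the raw Sherwood-based h_m to give the moisture-content-basis
    surface coefficient ``h_m_eff`` used by the solver boundary condition."""

    h_T: float
    h_m: float
    Re: float
    Pr: float
    Nu: float
    Sc: float
    Sh: float
    d: float
    f_s: float

    @property
    def h_m_eff(self) -> float:
        return self.f_s * self.h_m


def transfer_coefficients(
    air: AirState,
    d: float,
    f_s: float = 1.0,
    nu_exponent: float = 0.53,
) -> TransferCoefficients:
    """Ranz–Marshall film coefficients for a sphere of diameter ``d`` in a
    stream at velocity ``air.va``.

    Nu = 2 + 0.552 Re^nu_exponent Pr^(1/3); Sh = 2 + 0.552 Re^(1/2) Sc^(1/3).
    The Reynolds exponent of the Nusselt correlation defaults to 0.53 (the
    fitted value used for this material); ``nu_exponent=0.5`` recovers the
    symmetric classical form.
    """
    if d <= 0:
        raise DomainError(f"equivalent diameter d={d!r} must be positive")
    if f_s <= 0:
        raise DomainError(f"surface-resistance factor f_s={f_s!r} must be positive")
    Re = air.va * air.rho_a * d / air.mu_a
    Pr = air.mu_a * air.c_a / air.k_a
    Sc = air.mu_a / (air.rho_a * air.D_a)
    Nu = 2.0 + 0.552 * Re**nu_exponent * Pr ** (1.0 / 3.0)
    Sh = 2.0 + 0.552 * math.sqrt(Re) * Sc ** (1.0 / 3.0)
    return TransferCoefficients(
        h_T=Nu * air.k_a / d,
        h_m=Sh * air.D_a / d,
        Re=Re,
        Pr=Pr,
        Nu=Nu,
        Sc=Sc,
        Sh=Sh,
        d=d,
        f_s=f_s,
    )
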