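"""Panicle-layer water-cloud model: forward backscatter and analytic inversion.

The rice canopy is split into a panicle (ear) layer on top of a stem-and-leaf
layer. At Ku band (14.6 GHz, HH) penetration is shallow, so the total return
is modelled as canopy volume scattering saturating toward an asymptote ``C``,
plus an attenuated background term — either a bare-soil model ``A·exp(B·ms)``
or, for flooded paddies, a constant water-surface backscatter ``sigma0_bg``:

    sigma0 = C + (sigma0_bg - C) * exp(-2*D*(W1*h1 + W2*h2)/cos(theta))

where ``W_i*h_i`` is the areal water content (kg/m^2) of each layer, ``D``
the attenuation per unit areal water (m^2/kg) and ``theta`` the incidence
angle. The model is analytically invertible for total canopy water:

    W1*h1 + W2*h2 = a - b*ln(C - sigma0),  b = cos(theta)/(2D),
                                           a = b*ln(C - sigma0_bg).

Backscatter scale is explicit everywhere: the physical derivation lives in
linear power, but field curve fits are routinely done directly in dB, so
``WCMParams``/``InversionCoeffs`` carry a scale tag and mixing scales is a
checked error.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

__all__ = [
    "Scale",
    "Polarization",
    "RadarConfig",
    "CanopyLayer",
    "CanopyWater",
    "WCMParams",
    "InversionCoeffs",
    "InvalidLayerError",
    "DegenerateModelError",
    "SaturationError",
    "ScaleMismatchError",
    "InversionRangeWarning",
    "layer_unit_volume_water",
    "two_way_attenuation",
    "soil_backscatter",
    "forward_sigma0_full",
    "forward_sigma0_full_db",
    "forward_sigma0_flooded",
    "derive_inversion_coeffs",
    "invert_total_canopy_water",
]

DEFAULT_INCIDENCE_DEG = 50.0  # Ku-band MiniSAR acquisition geometry


class Scale(str, enum.Enum):
    """Backscatter scale a parameter set lives on."""

    DB = "dB"
    LINEAR = "linear"


class Polarization(str, enum.Enum):
    HH = "HH"
    HV = "HV"
    VH = "VH"
    VV = "VV"


class InvalidLayerError(ValueError):
    """Canopy layer violates its physical invariants."""


class DegenerateModelError(ValueError):
    """Model parameters admit no inversion (e.g. C <= sigma0_bg)."""


class SaturationError(ValueError):
    """Backscatter at or above the asymptote C: canopy water unresolvable."""


class ScaleMismatchError(ValueError):
    """dB and linear-power quantities mixed in one computation."""


class InversionRangeWarning(UserWarning):
    """Inverted canopy water fell outside the physically fitted range."""


@dataclass(frozen=True)
class RadarConfig:
    """Acquisition geometry and band of the SAR sensor.

    Defaults describe a Ku-band (14.6 GHz) HH system at 50 deg incidence
    with 0.3 m pixels.
    """

    frequency_ghz: float = 14.6
    polarization: Polarization = Polarization.HH
    incidence_deg: float = DEFAULT_INCIDENCE_DEG
    resolution_m: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.incidence_deg < 90.0:
            raise ValueError(f"incidence_deg must be in (0, 90), got {self.incidence_deg}")
        if self.frequency_ghz <= 0:
            raise ValueError("frequency_ghz must be positive")
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be positive")


@dataclass(frozen=True)
class CanopyLayer:
    """One vegetation layer described by destructive-sampling measurables.

    Parameters
    ----------
    h : float
        Layer height, m.
    m_wet, m_dry : float
        Per-plant wet and dry mass, kg/plant.
    n : float
        Plant density, plants/m^2.
    """

    h: float
    m_wet: float
    m_dry: float
    n: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise InvalidLayerError(f"layer height must be positive, got {self.h}")
        if self.m_dry < 0 or self.m_wet < self.m_dry:
            raise InvalidLayerError(
                f"need 0 <= m_dry <= m_wet, got m_dry={self.m_dry}, m_wet={self.m_wet}"
            )
        if self.n <= 0:
            raise InvalidLayerError(f"plant density must be positive, got {self.n}")

    @property
    def unit_volume_water(self) -> float:
        """Water per canopy volume, kg/m^3."""
        return layer_unit_volume_water(self)

    @property
    def areal_water(self) -> float:
        """Water per ground area W*h, kg/m^2."""
        return self.unit_volume_water * self.h


@dataclass(frozen=True)
class CanopyWater:
    """Water content of the two-layer canopy.

    ``W1``/``W2`` are unit-volume water (kg/m^3) of the panicle and
    stem-leaf layers; ``w1h1``/``w2h2`` the corresponding areal water
    (kg/m^2). The radar model only ever sees the areal quantities.
    """

    W1: float
    W2: float
    w1h1: float
    w2h2: float

    def __post_init__(self) -> None:
        for name in ("W1", "W2", "w1h1", "w2h2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_areal(self) -> float:
        return self.w1h1 + self.w2h2

    @classmethod
    def from_layers(cls, panicle: CanopyLayer, stem_leaf: CanopyLayer) -> "CanopyWater":
        w1 = layer_unit_volume_water(panicle)
        w2 = layer_unit_volume_water(stem_leaf)
        return cls(W1=w1, W2=w2, w1h1=w1 * panicle.h, w2h2=w2 * stem_leaf.h)

    @classmethod
    def from_areal(cls, w1h1: float, w2h2: float) -> "CanopyWater":
        """Build from areal water alone (heights unknown; W1/W2 set to 0-safe NaN-free values)."""
        return cls(W1=0.0, W2=0.0, w1h1=w1h1, w2h2=w2h2)


@dataclass(frozen=True)
class WCMParams:
    """Water-cloud model parameters.

    ``C`` is the volume-scattering asymptote (closed-canopy backscatter),
    ``D`` the attenuation coefficient per unit areal water (m^2/kg) and
    ``sigma0_bg`` the background (flooded-paddy water surface) backscatter.
    ``scale`` says whether C and sigma0_bg are linear power or dB. The
    optional ``soil_A``/``soil_B``/``ms`` triplet parameterises a bare-soil
    background ``A*exp(B*ms)`` for the non-flooded form.
    """

    C: float
    D: float
    sigma0_bg: float
    scale: Scale = Scale.DB
    soil_A: Optional[float] = None
    soil_B: Optional[float] = None
    ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"attenuation coefficient D must be positive, got {self.D}")
        object.__setattr__(self, "scale", Scale(self.scale))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "WCMParams":
        """Load from a parameter JSON with keys {C, D, sigma0_bg, scale, soil}."""
        obj = json.loads(Path(path).read_text())
        soil = obj.get("soil") or {}
        return cls(
            C=obj["C"],
            D=obj["D"],
            sigma0_bg=obj["sigma0_bg"],
            scale=Scale(obj.get("scale", "dB")),
            soil_A=soil.get("A"),
            soil_B=soil.get("B"),
            ms=soil.get("ms"),
        )

    def to_json(self, path: Union[str, Path], theta_deg: float = DEFAULT_INCIDENCE_DEG) -> None:
        soil = None
        if self.soil_A is not None:
            soil = {"A": self.soil_A, "B": self.soil_B, "ms": self.ms}
        Path(path).write_text(
            json.dumps(
                {
                    "C": self.C,
                    "D": self.D,
                    "sigma0_bg": self.sigma0_bg,
                    "scale": self.scale.value,
                    "theta_deg": theta_deg,
                    "soil": soil,
                },
                indent=2,
            )
        )


@dataclass(frozen=True)
class InversionCoeffs:
    """Coefficients of the closed-form canopy-water inversion.

    total areal water = a - b*ln(C - sigma0). ``b = cos(theta)/(2D)`` has
    units kg/m^2; ``a = b*ln(C - sigma0_bg)``.
    """

    a: float
    b: float
    C: float
    scale: Scale = Scale.DB

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"inversion scale coefficient b must be positive, got {self.b}")
        object.__setattr__(self, "scale", Scale(self.scale))


def _cos_theta(theta_deg: float) -> float:
    if not 0.0 <= theta_deg < 90.0:
        raise ValueError(f"incidence angle must be in [0, 90) degrees, got {theta_deg}")
    return math.cos(math.radians(theta_deg))


def layer_unit_volume_water(layer: CanopyLayer) -> float:
    """Unit-volume water content of a canopy layer, kg/m^3.

    W = (m_wet - m_dry) * n / h: per-plant water mass times plant density,
    spread over the layer height.
    """
    return (layer.m_wet - layer.m_dry) * layer.n / layer.h


def two_way_attenuation(D: float, areal_water: float, theta_deg: float) -> float:
    """Two-way canopy transmissivity tau^2 = exp(-2*D*W*h / cos(theta)).

    Fraction of power surviving the down-and-up passage through a layer
    holding ``areal_water`` kg/m^2 of water, along a slant path at
    ``theta_deg`` incidence. Always in (0, 1]; multiplicative across layers.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if areal_water < 0:
        raise ValueError("areal_water must be >= 0")
    return math.exp(-2.0 * D * areal_water / _cos_theta(theta_deg))


def soil_backscatter(A: float, B: float, ms: float) -> float:
    """Bare-soil backscatter A*exp(B*ms) in linear power.

    ``ms`` is volumetric soil moisture; A and B wrap band, incidence,
    polarization and roughness dependence.
    """
    return A * math.exp(B * ms)


def forward_sigma0_full(params: WCMParams, water: CanopyWater, theta_deg: float = DEFAULT_INCIDENCE_DEG) -> float:
    """Full two-layer forward model over a soil background, linear power.

    sigma0 = C*(1 - tau^2) + A*exp(B*ms)*tau^2 with tau^2 the two-way
    attenuation of the whole canopy (both layers; exponential additivity).
    Requires linear-scale params carrying the soil triplet.
    """
    if params.scale is not Scale.LINEAR:
        raise ScaleMismatchError("full forward model is defined on linear-power parameters")
    if params.soil_A is None or params.soil_B is None or params.ms is None:
        raise ValueError("params must carry soil_A, soil_B and ms for the soil-background model")
    tau2 = two_way_attenuation(params.D, water.total_areal, theta_deg)
    return params.C * (1.0 - tau2) + soil_backscatter(params.soil_A, params.soil_B, params.ms) * tau2


def forward_sigma0_full_db(params: WCMParams, water: CanopyWater, theta_deg: float = DEFAULT_INCIDENCE_DEG) -> float:
    """Full forward model expressed in dB: 10*log10(sigma0_linear)."""
    sigma0 = forward_sigma0_full(params, water, theta_deg)
    if sigma0 <= 0:
        raise ValueError(f"linear-power sigma0 must be positive for dB conversion, got {sigma0}")
    return 10.0 * math.log10(sigma0)


def forward_sigma0_flooded(
    params: WCMParams,
    total_areal_water: float,
    theta_deg: float = DEFAULT_INCIDENCE_DEG,
) -> float:
    """Flooded-paddy forward model: water surface as the background.

    sigma0 = C + (sigma0_bg - C) * exp(-2*D*total/cos(theta)). Works on
    whichever scale ``params`` declares (the curve is routinely fitted
    directly in dB). Strictly increasing in total water when C > sigma0_bg,
    running from sigma0_bg (bare water) to C (closed canopy).
    """
    if total_areal_water < 0:
        raise ValueError("total areal water must be >= 0")
    tau2 = two_way_attenuation(params.D, total_areal_water, theta_deg)
    return params.C + (params.sigma0_bg - params.C) * tau2


def derive_inversion_coeffs(params: WCMParams, theta_deg: float = DEFAULT_INCIDENCE_DEG) -> InversionCoeffs:
    """Closed-form inversion coefficients (a, b) from the flooded model.

    b = cos(theta)/(2D); a = b*ln(C - sigma0_bg). Requires C > sigma0_bg,
    otherwise the model is flat or decreasing and carries no water signal.
    """
    if params.C <= params.sigma0_bg:
        raise DegenerateModelError(
            f"inversion needs C > sigma0_bg, got C={params.C}, sigma0_bg={params.sigma0_bg}"
        )
    b = _cos_theta(theta_deg) / (2.0 * params.D)
    a = b * math.log(params.C - params.sigma0_bg)
    return InversionCoeffs(a=a, b=b, C=params.C, scale=params.scale)


def invert_total_canopy_water(sigma0: float, coeffs: InversionCoeffs) -> float:
    """Total canopy areal water from backscatter: a - b*ln(C - sigma0), kg/m^2.

    Exact algebraic inverse of :func:`forward_sigma0_flooded`. ``sigma0``
    must lie below the asymptote C (saturation); a negative result means
    the observation fell below the fitted range and is returned as-is with
    an :class:`InversionRangeWarning` rather than clipped.
    """
    if sigma0 >= coeffs.C:
        raise SaturationError(
            f"sigma0={sigma0} at or above asymptote C={coeffs.C}: canopy saturated"
        )
    total = coeffs.a - coeffs.b * math.log(coeffs.C - sigma0)
    if total < 0:
        warnings.warn(
            f"inverted canopy water {total:.4g} kg/m^2 is negative (sigma0 below fitted range)",
            InversionRangeWarning,
            stacklevel=2,
        )
    return total
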