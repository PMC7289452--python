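"""Tissue optical properties and derived transport quantities.

Holds (mu_a, mu_s, g, n) per tissue region and computes the standard
derived quantities used throughout cavity dosimetry: the reduced
scattering coefficient mu_s' = mu_s (1 - g), the single-scattering
albedo mu_s / (mu_s + mu_a), and the diffusion-theory effective
attenuation coefficient mu_eff = sqrt(3 mu_a (mu_a + mu_s')).

All coefficients are in mm^-1. The built-in preset is the 525-nm
green-light property set for bladder wall, adipose tissue and a
water-filled lumen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

__all__ = [
    "OpticalProperties",
    "PropertyMap",
    "preset_properties",
    "albedo",
    "reduced_scattering",
    "effective_attenuation",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one tissue region.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1. Non-negative.
    mu_s : float
        Scattering coefficient, mm^-1. Non-negative.
    g : float
        Henyey-Greenstein scattering anisotropy, -1 < g < 1.
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must satisfy -1 < g < 1")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, mm^-1."""
        return self.mu_a + self.mu_s

    @property
    def mu_s_reduced(self) -> float:
        return reduced_scattering(self)

    @property
    def albedo(self) -> float:
        return albedo(self)

    @property
    def mu_eff(self) -> float:
        return effective_attenuation(self)


#: Region labels used across the package.
REGIONS = ("void", "wall", "adipose")


@dataclass(frozen=True)
class PropertyMap:
    """Assignment of optical properties to the three cavity regions."""

    void: OpticalProperties
    wall: OpticalProperties
    adipose: OpticalProperties

    def __getitem__(self, region: str) -> OpticalProperties:
        if region not in REGIONS:
            raise KeyError(f"unknown region {region!r}; expected one of {REGIONS}")
        return getattr(self, region)

    def as_dict(self) -> Dict[str, OpticalProperties]:
        return {r: self[r] for r in REGIONS}


# 525-nm property set: bladder wall, adipose tissue, water-filled lumen.
_PRESETS = {
    "bladder_525nm": PropertyMap(
        void=OpticalProperties(mu_a=0.000041, mu_s=0.000017, g=0.8, n=1.33),
        wall=OpticalProperties(mu_a=0.45, mu_s=14.6, g=0.9, n=1.37),
        adipose=OpticalProperties(mu_a=0.149, mu_s=6.9, g=0.9, n=1.37),
    )
}


def preset_properties(name: str = "bladder_525nm") -> PropertyMap:
    """Return a named optical-property preset.

    ``bladder_525nm`` is the green-light (525 nm) set: bladder wall
    mu_a = 0.45 mm^-1, mu_s = 14.6 mm^-1; adipose mu_a = 0.149 mm^-1,
    mu_s = 6.9 mm^-1 (both with g = 0.9, n = 1.37); lumen filled with
    water (mu_a = 4.1e-5 mm^-1, mu_s = 1.7e-5 mm^-1, g = 0.8, n = 1.33).
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def albedo(props: OpticalProperties) -> float:
    """Single-scattering albedo a = mu_s / (mu_s + mu_a), in [0, 1]."""
    denom = props.mu_s + props.mu_a
    if denom <= 0.0:
        raise ValueError("albedo undefined: mu_a + mu_s must be positive")
    return props.mu_s / denom


def reduced_scattering(props: OpticalProperties) -> float:
    """Reduced (transport) scattering coefficient mu_s' = mu_s (1 - g), mm^-1."""
    return props.mu_s * (1.0 - props.g)


def effective_attenuation(props: OpticalProperties) -> float:
    """Diffusion-theory effective attenuation mu_eff, mm^-1.

    mu_eff = sqrt(3 mu_a (mu_a + mu_s')). Valid in the diffusive regime
    (mu_s' >> mu_a); returned regardless, as the standard closed form.
    Raises if mu_a == 0, where diffuse light is unattenuated.
    """
    if props.mu_a == 0.0:
        raise ValueError("mu_eff is zero for a non-absorbing medium (mu_a = 0)")
    return math.sqrt(3.0 * props.mu_a * (props.mu_a + reduced_scattering(props)))
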