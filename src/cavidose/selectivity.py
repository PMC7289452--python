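"""Photodynamic-threshold selectivity model.

Tissue necrosis under PDT follows a threshold rule: a tissue dies where
the absorbed photon density exceeds its photodynamic threshold dose T
(hnu cm^-3) scaled by the local photosensitizer concentration. With a
tumor on the inner wall surface and normal tissue (urothelium, muscle)
at depth d behind it, selectivity holds wherever

    (T_tumor / [PS]_tumor) * (phi(0) / phi(d)) < T_normal / [PS]_normal

i.e. the fluence ratio accumulated across the intervening tissue,
phi(0)/phi(d), stays below the allowable ratio

    SUR * (T_normal / T_tumor),

where SUR = [PS]_tumor / [PS]_normal is the specific uptake ratio.
Defaults are the preclinical rat-bladder values for the ruthenium
photosensitizer TLD1433: uptakes 77 and 0.4 mg kg^-1 (SUR ~192),
thresholds 2.121, 0.161 and 0.128 x 10^18 hnu cm^-3 for tumor,
urothelium and muscle.

The attainable treatment depth converts the allowable fluence ratio
into millimetres through the effective attenuation length mu_eff^-1.
Three modes are provided: the rule-of-thumb 2.5 attenuation lengths
("rule_of_thumb" mode, default mu_eff^-1 = 750 um at green wavelengths, giving
~2 mm), the planar exponential closed form d = ln(ratio) / mu_eff, and
a spherical mode that adds the (R/(R+d))^2 divergence of a cavity wall.
mu_eff^-1 is an explicit parameter rather than being forced to the
diffusion-theory value of any particular property set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ThresholdModel",
    "FluenceDepthProfile",
    "specific_uptake_ratio",
    "threshold_ratio",
    "allowable_fluence_ratio",
    "selectivity_depth",
    "check_selectivity_profile",
    "TLD1433_DEFAULTS",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Photodynamic threshold doses and photosensitizer uptakes.

    Thresholds in hnu cm^-3 (units cancel in every ratio), uptakes in
    mg kg^-1.
    """

    T_tumor: float = 2.121e18
    T_urothelium: float = 0.161e18
    T_muscle: float = 0.128e18
    uptake_tumor: float = 77.0
    uptake_normal: float = 0.4

    def __post_init__(self):
        vals = (
            self.T_tumor,
            self.T_urothelium,
            self.T_muscle,
            self.uptake_tumor,
            self.uptake_normal,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("thresholds and uptakes must be positive")


#: preclinical default parameter set
TLD1433_DEFAULTS = ThresholdModel()


@dataclass
class FluenceDepthProfile:
    """Fluence ratio phi(0)/phi(d) versus depth below the inner surface.

    The ratio is >= 1 and non-decreasing in depth. Build analytically
    (:meth:`exponential`) or from transport depth shells
    (:meth:`from_depth_absorption`).
    """

    depth_mm: np.ndarray
    fluence_ratio: np.ndarray  # phi(0) / phi(d)

    def __post_init__(self):
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.fluence_ratio = np.asarray(self.fluence_ratio, dtype=float)
        if np.any(self.fluence_ratio < 1.0 - 1e-9):
            raise ValueError("fluence ratio must be >= 1 at all depths")

    def ratio_at(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if np.any(d > self.depth_mm[-1] + 1e-12):
            raise ValueError("profile does not cover the requested depth")
        out = np.interp(d, self.depth_mm, self.fluence_ratio)
        return out if out.ndim else float(out)

    @classmethod
    def exponential(
        cls,
        mu_eff_inv_mm: float,
        depth_max_mm: float = 5.0,
        n: int = 201,
        sphere_radius_mm: Optional[float] = None,
    ) -> "FluenceDepthProfile":
        """phi(0)/phi(d) = exp(d/mu_eff_inv), optionally times the
        spherical divergence ((R+d)/R)^2."""
        d = np.linspace(0.0, depth_max_mm, n)
        ratio = np.exp(d / mu_eff_inv_mm)
        if sphere_radius_mm is not None:
            ratio = ratio * ((sphere_radius_mm + d) / sphere_radius_mm) ** 2
        return cls(depth_mm=d, fluence_ratio=ratio)

    @classmethod
    def from_depth_absorption(
        cls, depth_mm: np.ndarray, absorption_density: np.ndarray
    ) -> "FluenceDepthProfile":
        """Profile from a scored absorption-depth curve.

        Within a region of uniform mu_a the fluence is proportional to
        the absorbed energy density, so phi(0)/phi(d) = A(0)/A(d). The
        curve is clipped to its monotone non-increasing envelope before
        forming ratios (Monte Carlo noise can produce local inversions).
        """
        a = np.asarray(absorption_density, dtype=float)
        d = np.asarray(depth_mm, dtype=float)
        keep = a > 0
        a = np.minimum.accumulate(a[keep])
        d = d[keep]
        ratio = np.maximum(a[0] / a, 1.0)
        return cls(depth_mm=d, fluence_ratio=ratio)


def specific_uptake_ratio(model: ThresholdModel) -> float:
    """SUR = tumor uptake / normal uptake (defaults: 77/0.4 = 192.5)."""
    return model.uptake_tumor / model.uptake_normal


def threshold_ratio(model: ThresholdModel, normal_tissue: str = "urothelium") -> float:
    """T_tumor / T_normal: how many more photons the tumor needs.

    The worst case against urothelium is ~13.2 with the default
    thresholds.
    """
    if normal_tissue == "urothelium":
        return model.T_tumor / model.T_urothelium
    if normal_tissue == "muscle":
        return model.T_tumor / model.T_muscle
    raise ValueError("normal_tissue must be 'urothelium' or 'muscle'")


def allowable_fluence_ratio(
    SUR: float, threshold_ratio_inverse: float
) -> float:
    """Maximum permitted phi(0)/phi(d).

    ``threshold_ratio_inverse`` is T_normal / T_tumor (0.0757 for the
    default tumor/urothelium pair as printed; 0.161/2.121 = 0.0759 from
    the rounded thresholds). Selectivity at depth d requires
    phi(0)/phi(d) below the returned value (192 x 0.0757 ~ 14.5).
    """
    if SUR <= 0 or threshold_ratio_inverse <= 0:
        raise ValueError("SUR and threshold ratio must be positive")
    return SUR * threshold_ratio_inverse


def selectivity_depth(
    allowable_ratio: float,
    mu_eff_inv_mm: float = 0.75,
    mode: str = "rule_of_thumb",
    sphere_radius_mm: Optional[float] = None,
) -> float:
    """Treatment depth (mm) compatible with the allowable fluence ratio.

    ``rule_of_thumb``
        2.5 attenuation lengths: d = 2.5 * mu_eff^-1
        (~2 mm at 750 um).
    ``planar``
        Planar exponential attenuation: d = ln(ratio) * mu_eff^-1.
    ``spherical``
        Adds cavity-wall divergence: solves
        (R/(R+d))^2 exp(-d/mu_eff_inv) = 1/ratio for d; always at or
        below the planar depth.
    """
    if mu_eff_inv_mm <= 0:
        raise ValueError("mu_eff_inv must be positive")
    if mode == "rule_of_thumb":
        return 2.5 * mu_eff_inv_mm
    if allowable_ratio < 1.0:
        raise ValueError("allowable fluence ratio must be >= 1")
    if mode == "planar":
        return float(np.log(allowable_ratio)) * mu_eff_inv_mm
    if mode == "spherical":
        if sphere_radius_mm is None or sphere_radius_mm <= 0:
            raise ValueError("spherical mode needs a positive sphere_radius_mm")
        if allowable_ratio == 1.0:
            return 0.0

        def f(d):
            return (
                d / mu_eff_inv_mm
                + 2.0 * np.log((sphere_radius_mm + d) / sphere_radius_mm)
                - np.log(allowable_ratio)
            )

        d_hi = float(np.log(allowable_ratio)) * mu_eff_inv_mm  # planar bound
        return float(brentq(f, 0.0, d_hi))
    raise ValueError("mode must be 'rule_of_thumb', 'planar' or 'spherical'")


def check_selectivity_profile(
    model: ThresholdModel,
    profile: FluenceDepthProfile,
    depth_max_mm: float,
    normal_tissue: str = "urothelium",
    n_depths: int = 101,
) -> Dict:
    """Evaluate the selectivity criterion along a fluence-depth profile.

    At each depth the criterion holds iff phi(0)/phi(d) is below
    SUR * T_normal / T_tumor; the margin is the allowable ratio divided
    by the actual ratio (> 1 where selective).
    """
    if depth_max_mm > profile.depth_mm[-1] + 1e-12:
        raise ValueError("profile shorter than requested depth range")
    allow = allowable_fluence_ratio(
        specific_uptake_ratio(model), 1.0 / threshold_ratio(model, normal_tissue)
    )
    d = np.linspace(0.0, depth_max_mm, n_depths)
    ratio = profile.ratio_at(d)
    margin = allow / ratio
    return {
        "depth_mm": d,
        "fluence_ratio": ratio,
        "selective": ratio < allow,
        "margin": margin,
        "allowable_ratio": allow,
        "max_selective_depth_mm": float(d[ratio < allow].max())
        if np.any(ratio < allow)
        else 0.0,
    }
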