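"""Monte Carlo photon-packet transport in the bladder cavity.

An isotropic point emitter in the void launches photon packets that
propagate through the void, wall and adipose regions with
Henyey-Greenstein scattering, absorption by weight attenuation, and
Fresnel/Snell handling at the void-wall refractive-index step. Scored
quantities:

* per-patch surface irradiance (mW cm^-2) — every incidence of packet
  weight on the inner surface, i.e. both primary light and light
  diffusely re-emitted by the wall, matching the integrating-sphere
  multiplication picture;
* the primary (unscattered, first-incidence) component separately;
* volumetric absorption on concentric depth shells below the inner
  surface, for fluence-depth-profile work;
* absorbed/escaped weight totals, which must sum to the launched weight
  to 1e-6 relative on every run.

An idealized Lambertian-wall mode (:func:`run_lambertian_wall`) treats
a spherical wall as a diffuse reflector with reflectance rho; its
multiplication factor has the closed form 1/(1-rho) and serves as an
analytic oracle for the cavity build-up physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .geometry import BladderGeometry, SurfacePatches, region_at
from .optics import PropertyMap

__all__ = [
    "SourceSpec",
    "TransportConfig",
    "DoseMaps",
    "run_transport",
    "run_lambertian_wall",
    "sample_hg_deflection",
    "fresnel_reflectance",
]

#: mm^-2 -> cm^-2
_MM2_TO_CM2 = 100.0


@dataclass(frozen=True)
class SourceSpec:
    """Isotropic point emitter.

    position : 3-vector, mm (must lie in the void)
    power : optical power, mW
    """

    position: np.ndarray
    power: float
    emission: str = "isotropic"

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.power < 0:
            raise ValueError("source power must be non-negative")
        if self.emission != "isotropic":
            raise ValueError("only isotropic emission is supported")


@dataclass(frozen=True)
class TransportConfig:
    """Run-size and termination parameters.

    n_packets : photon packets to launch (desk-scale default 1e6)
    seed : RNG seed; identical (config, seed) reproduces DoseMaps bitwise
    weight_cutoff : packets below this weight deposit their residual
        locally and terminate (keeps per-run energy bookkeeping exact)
    max_path_mm : path-length guard per packet
    depth_bin_mm : depth-shell width for volumetric absorption scoring
    """

    n_packets: int = 1_000_000
    seed: int = 0
    weight_cutoff: float = 1e-4
    max_path_mm: float = 2.0e4
    depth_bin_mm: float = 0.1

    def __post_init__(self):
        if self.n_packets < 1:
            raise ValueError("n_packets must be >= 1")
        if not 0 < self.weight_cutoff < 1:
            raise ValueError("weight_cutoff must be in (0, 1)")


@dataclass
class DoseMaps:
    """Scored output of one transport run."""

    surface_irradiance: np.ndarray  # per patch, mW cm^-2
    primary_irradiance: np.ndarray  # unscattered first-incidence component
    surface_irradiance_half: np.ndarray  # first-half-packet estimate (MC error)
    patch_areas: np.ndarray  # mm^2
    depth_edges: np.ndarray  # mm, shell edges below the inner surface
    volumetric_absorption: np.ndarray  # mW mm^-3 per shell
    absorbed_fraction: float
    escaped_fraction: float
    n_packets_run: int
    seed: int
    source_power: float  # mW
    sensor_raw: Optional[np.ndarray] = None  # accumulated response weights
    config: TransportConfig = field(default_factory=TransportConfig)

    @property
    def conservation_residual(self) -> float:
        """|absorbed + escaped - 1|; should be < 1e-6 on every run."""
        return abs(self.absorbed_fraction + self.escaped_fraction - 1.0)

    @property
    def mean_wall_irradiance(self) -> float:
        """Area-weighted mean surface irradiance, mW cm^-2."""
        return float(
            np.average(self.surface_irradiance, weights=self.patch_areas)
        )

    @property
    def multiplication_factor(self) -> float:
        """Total over primary scored surface power (integrating-sphere
        build-up factor)."""
        prim = float(np.sum(self.primary_irradiance * self.patch_areas))
        if prim == 0.0:
            return float("nan")
        return float(np.sum(self.surface_irradiance * self.patch_areas)) / prim

    def halves(self):
        """Two statistically independent half-run irradiance maps.

        The difference between them gauges the Monte Carlo error of any
        derived statistic.
        """
        a = self.surface_irradiance_half
        b = 2.0 * self.surface_irradiance - a  # total = (a + b)/2
        return a, b

    def to_csv(self, path) -> None:
        """Per-patch table: patch id, area (mm^2), total and primary
        irradiance (mW cm^-2)."""
        import pandas as pd

        pd.DataFrame(
            {
                "patch_id": np.arange(len(self.surface_irradiance)),
                "area_mm2": self.patch_areas,
                "irradiance_mw_cm2": self.surface_irradiance,
                "primary_irradiance_mw_cm2": self.primary_irradiance,
            }
        ).to_csv(path, index=False)

    def summary_json(self, path) -> None:
        """Machine-readable run record: seed, config, conservation."""
        import dataclasses
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": int(self.seed),
                    "n_packets": int(self.n_packets_run),
                    "source_power_mw": self.source_power,
                    "config": dataclasses.asdict(self.config),
                    "absorbed_fraction": self.absorbed_fraction,
                    "escaped_fraction": self.escaped_fraction,
                    "conservation_residual": self.conservation_residual,
                    "mean_wall_irradiance_mw_cm2": self.mean_wall_irradiance,
                },
                fh,
                indent=2,
            )

    def depth_profile(self, r_reference_mm: Optional[float] = None):
        """(depth centers mm, absorbed power density mW mm^-3).

        Shell volumes use the sphere-equivalent inner area scaled by
        ((r + d)/r)^2; pass ``r_reference_mm`` to override the
        sphere-equivalent radius.
        """
        centers = 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])
        return centers, self.volumetric_absorption


def _region_props(property_map: PropertyMap):
    mua = np.empty(3)
    mus = np.empty(3)
    g = np.empty(3)
    n = np.empty(3)
    for i, region in enumerate(("void", "wall", "adipose")):
        p = property_map[region]
        if not all(np.isfinite([p.mu_a, p.mu_s, p.g, p.n])):
            raise ValueError(f"non-finite optical properties for region {region!r}")
        mua[i], mus[i], g[i], n[i] = p.mu_a, p.mu_s, p.g, p.n
    return mua, mus, g, n


def _empty_sensor_arrays(n_patches: int):
    return (
        np.zeros((0, 3)),
        np.zeros(0, dtype=np.int64),
        np.zeros(0),
        np.zeros(n_patches + 1, dtype=np.int64),
        np.zeros(0, dtype=np.int64),
    )


def run_transport(
    geometry: BladderGeometry,
    property_map: PropertyMap,
    source: SourceSpec,
    patches: SurfacePatches,
    config: TransportConfig = TransportConfig(),
    sensor_bank=None,
) -> DoseMaps:
    """Run the packet engine and score dose maps.

    ``sensor_bank`` is an optional :class:`cavidose.sensors.SensorBank`
    whose per-sensor angular responses are accumulated in-flight; pass
    it when virtual sensor readings are wanted without a crossing log.
    """
    if region_at(geometry, source.position) != "void":
        raise ValueError("source position must lie inside the void")
    mua, mus, g, n = _region_props(property_map)

    t_wall = geometry.wall_thickness_mm
    t_out = t_wall + geometry.adipose_thickness_mm
    n_depth = max(1, int(np.ceil(t_out / config.depth_bin_mm)))
    patch_w = np.zeros(patches.n_patches)
    patch_w_half = np.zeros(patches.n_patches)
    primary_w = np.zeros(patches.n_patches)
    depth_abs = np.zeros(n_depth)

    if sensor_bank is None:
        sens_axes, sens_kind, sens_coscut, ps_ptr, ps_idx = _empty_sensor_arrays(
            patches.n_patches
        )
        sens_accum = np.zeros(0)
    else:
        sens_axes, sens_kind, sens_coscut, ps_ptr, ps_idx = sensor_bank.kernel_arrays(
            patches
        )
        sens_accum = np.zeros(sens_axes.shape[0])

    n_half = config.n_packets // 2
    absorbed, escaped = _kernels.transport_kernel(
        geometry.kind_code,
        geometry.base_params,
        geometry.lobe_dirs,
        geometry.lobe_amps,
        geometry.lobe_kappas,
        t_wall,
        t_out,
        geometry.angular_grad_bound,
        geometry.r_min,
        mua,
        mus,
        g,
        n,
        source.position[0],
        source.position[1],
        source.position[2],
        patches.patch_dirs,
        config.n_packets,
        n_half,
        int(config.seed) & 0x7FFFFFFF,
        config.weight_cutoff,
        config.max_path_mm,
        config.depth_bin_mm,
        sens_axes,
        sens_kind,
        sens_coscut,
        ps_ptr,
        ps_idx,
        patch_w,
        patch_w_half,
        primary_w,
        depth_abs,
        sens_accum,
    )

    power_per_packet = source.power / config.n_packets  # mW
    irr = patch_w * power_per_packet / patches.patch_areas * _MM2_TO_CM2
    irr_prim = primary_w * power_per_packet / patches.patch_areas * _MM2_TO_CM2
    irr_half = (
        patch_w_half
        * (source.power / max(n_half, 1))
        / patches.patch_areas
        * _MM2_TO_CM2
    )

    edges = np.arange(n_depth + 1) * config.depth_bin_mm
    r_eq = (3.0 * geometry.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = (
        patches.total_area * ((r_eq + centers) / r_eq) ** 2 * config.depth_bin_mm
    )
    vol_abs = depth_abs * power_per_packet / shell_vol  # mW mm^-3

    return DoseMaps(
        surface_irradiance=irr,
        primary_irradiance=irr_prim,
        surface_irradiance_half=irr_half,
        patch_areas=patches.patch_areas.copy(),
        depth_edges=edges,
        volumetric_absorption=vol_abs,
        absorbed_fraction=absorbed / config.n_packets,
        escaped_fraction=escaped / config.n_packets,
        n_packets_run=config.n_packets,
        seed=config.seed,
        source_power=source.power,
        sensor_raw=sens_accum if sensor_bank is not None else None,
        config=config,
    )


def run_lambertian_wall(
    geometry: BladderGeometry,
    source: SourceSpec,
    rho: float,
    patches: SurfacePatches,
    config: TransportConfig = TransportConfig(),
) -> DoseMaps:
    """Idealized integrating-sphere oracle: clear void, Lambertian wall.

    Requires a spherical geometry. Total scored surface power is the
    primary power times the geometric series 1/(1-rho).
    """
    if geometry.shape_kind != "sphere":
        raise ValueError("Lambertian-wall mode requires a spherical geometry")
    if not 0.0 <= rho < 1.0:
        raise ValueError("wall reflectance rho must be in [0, 1)")
    if region_at(geometry, source.position) != "void":
        raise ValueError("source position must lie inside the void")

    radius = float(geometry.base_params[0])
    patch_w = np.zeros(patches.n_patches)
    patch_w_half = np.zeros(patches.n_patches)
    primary_w = np.zeros(patches.n_patches)
    n_half = config.n_packets // 2
    absorbed, escaped = _kernels.lambertian_kernel(
        radius,
        source.position[0],
        source.position[1],
        source.position[2],
        rho,
        patches.patch_dirs,
        config.n_packets,
        n_half,
        int(config.seed) & 0x7FFFFFFF,
        100_000,
        patch_w,
        patch_w_half,
        primary_w,
    )
    power_per_packet = source.power / config.n_packets
    irr = patch_w * power_per_packet / patches.patch_areas * _MM2_TO_CM2
    irr_prim = primary_w * power_per_packet / patches.patch_areas * _MM2_TO_CM2
    irr_half = (
        patch_w_half
        * (source.power / max(n_half, 1))
        / patches.patch_areas
        * _MM2_TO_CM2
    )
    return DoseMaps(
        surface_irradiance=irr,
        primary_irradiance=irr_prim,
        surface_irradiance_half=irr_half,
        patch_areas=patches.patch_areas.copy(),
        depth_edges=np.array([0.0, geometry.wall_thickness_mm]),
        volumetric_absorption=np.zeros(1),
        absorbed_fraction=absorbed / config.n_packets,
        escaped_fraction=escaped / config.n_packets,
        n_packets_run=config.n_packets,
        seed=config.seed,
        source_power=source.power,
        config=config,
    )


def sample_hg_deflection(g: float, u) -> np.ndarray:
    """Henyey-Greenstein cos(theta) from uniform deviates u in [0, 1).

    For g = 0 the phase function is isotropic, cos(theta) = 2u - 1;
    otherwise the standard inverse-CDF form is used. E[cos(theta)] = g.
    """
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must satisfy |g| < 1")
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-6:
        ct = 2.0 * u - 1.0
    else:
        f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - f * f) / (2.0 * g)
    return np.clip(ct, -1.0, 1.0)


def fresnel_reflectance(n1: float, n2: float, cos_incident) -> np.ndarray:
    """Unpolarized Fresnel power reflectance at an n1 -> n2 interface.

    Returns 1 beyond the total-internal-reflection angle. Vectorized in
    ``cos_incident`` (the magnitude of the incidence cosine).
    """
    if n1 < 1.0 or n2 < 1.0:
        raise ValueError("refractive indices must be >= 1")
    ci = np.abs(np.asarray(cos_incident, dtype=float))
    if np.any(ci > 1.0 + 1e-12):
        raise ValueError("|cos_incident| must be <= 1")
    ci = np.clip(ci, 0.0, 1.0)
    st2 = (n1 / n2) ** 2 * (1.0 - ci**2)
    tir = st2 >= 1.0
    ct = np.sqrt(np.clip(1.0 - st2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
        rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    out = np.where(tir, 1.0, 0.5 * (rs**2 + rp**2))
    return out if out.ndim else float(out)
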